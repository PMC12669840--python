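"""End-to-end study replica: population -> landmarks -> GPA/symmetry/PCA ->
metrics -> tests -> PC1-extreme pair -> comparative FEA -> report.

Every stage writes its artifacts under the configured output directory; the
whole run is deterministic given the config (one seed drives specimen
generation, another the ANOVA permutations).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fea, landmarks as lm, metrics as bm, procrustes as gpa, scaling, stats
from .synthetic import (BillParams, BillSpecimen, PopulationSpec,
                        default_population_spec, export_specimen,
                        generate_surface, generate_volume, sample_population)


@dataclass
class StudyConfig:
    population: PopulationSpec
    landmark_n: int = 60
    anova_perms: int = 999
    seed: int = 0
    exclude_shape: list[str] = field(default_factory=list)
    surface_resolution: dict = field(default_factory=lambda: {"n_u": 80})
    volume_resolution: dict = field(default_factory=dict)
    fe_order: int = 2
    with_buckling: bool = True
    reference_group: str = "F"
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["population"]["group_means"] = {
            k: asdict(v) if isinstance(v, BillParams) else v
            for k, v in self.population.group_means.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        pop = dict(d.pop("population"))
        pop["group_means"] = {k: BillParams(**v) for k, v in pop["group_means"].items()}
        return cls(population=PopulationSpec(**pop), **d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # where results land is not scientific state
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def default_config(seed: int = 0, **kw) -> StudyConfig:
    return StudyConfig(population=default_population_spec(seed=seed), seed=seed, **kw)


def select_extremes(
    scores_pc1: np.ndarray, group_labels: np.ndarray, ids: list[str]
) -> tuple[str, str]:
    """Specimens at the minimum and maximum of PC1, one per group.

    If both extremes fall in the same group, the nearer one is replaced by the
    most extreme member of the other group on its side.  Ties break on
    specimen id (lexicographic).  PC1 sign flips swap min/max but return the
    same pair.
    """
    scores = np.asarray(scores_pc1, dtype=float)
    groups = np.asarray(group_labels)
    ids = list(ids)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups to select an extreme pair")

    def argext(mask, sign):
        vals = np.where(mask, sign * scores, -np.inf)
        best = vals.max()
        cand = np.where(np.isclose(vals, best) & mask)[0]
        return cand[np.argmin([ids[i] for i in cand])] if len(cand) > 1 else cand[0]

    all_mask = np.ones(len(scores), dtype=bool)
    i_min = argext(all_mask, -1.0)
    i_max = argext(all_mask, +1.0)
    if groups[i_min] == groups[i_max]:
        other = groups != groups[i_min]
        # keep the overall-more-extreme one, replace the other from the other group
        if abs(scores[i_min] - np.median(scores)) >= abs(scores[i_max] - np.median(scores)):
            i_max = argext(other, +1.0)
        else:
            i_min = argext(other, -1.0)
    return ids[i_min], ids[i_max]


@dataclass
class StudyReport:
    config_digest: str
    n_specimens: int
    n_shape: int
    pct_variance: list[float]
    pc1_group_means: dict[str, float]
    anova_sex: dict
    metric_tests: dict
    spearman_sharpness_angle: dict
    extremes: dict
    fe_comparisons: dict
    provenance: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=float)


def run_study(config: StudyConfig) -> StudyReport:
    """Execute every stage of the study on a synthetic population."""
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    log = logging.getLogger("billmech.pipeline")

    def stage(name, fn, *a, **kw):
        t0 = time.perf_counter()
        try:
            result = fn(*a, **kw)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        log.info("stage %s: %.2f s", name, time.perf_counter() - t0)
        return result

    # 1. population ------------------------------------------------------
    specimens = stage("generate", sample_population, config.population,
                      **config.surface_resolution)
    by_id = {sp.id: sp for sp in specimens}
    if out:
        for sp in specimens:
            export_specimen(sp, out / "specimens")

    # 2. landmarks (aligned, resampled, merged) ---------------------------
    shape_ids = [sp.id for sp in specimens if sp.id not in set(config.exclude_shape)]
    configs = {}
    for sid in shape_ids:
        sp = by_id[sid]
        aligned, _, _ = lm.align_to_axis(sp.contours)
        configs[sid] = stage("landmarks", lm.configuration_from_contours,
                             aligned, config.landmark_n)
    if out:
        lm.write_configurations_csv(out / "landmarks.csv", configs)

    # 3. GPA + symmetry + PCA ---------------------------------------------
    fit = stage("shape", gpa.generalized_procrustes,
                [configs[s] for s in shape_ids], specimen_ids=shape_ids)
    proto = configs[shape_ids[0]]
    sym = gpa.bilateral_symmetry(fit, proto)
    space = gpa.shape_pca(sym.symmetric)
    sexes = np.array([by_id[s].sex for s in shape_ids])
    if out:
        np.savetxt(out / "pc_scores.csv",
                   np.column_stack([space.scores]), delimiter=",")
        np.savetxt(out / "eigenvalues.csv", space.eigenvalues, delimiter=",")
        np.savetxt(out / "aligned_coords.csv",
                   fit.aligned.reshape(len(shape_ids), -1), delimiter=",")
        import trimesh

        trimesh.PointCloud(fit.consensus).export(out / "consensus.ply")
        with open(out / "gpa_fit.json", "w") as fh:
            json.dump({"specimen_ids": shape_ids,
                       "centroid_sizes": fit.centroid_sizes.tolist(),
                       "n_slide_iterations": fit.n_slide_iterations,
                       "converged": fit.converged,
                       "ss_history": fit.ss_history}, fh, indent=2)

    # 4. metrics -----------------------------------------------------------
    table = stage("metrics", bm.metrics_table, specimens)
    if out:
        table.to_csv(out / "metrics.csv")

    # 5. statistics --------------------------------------------------------
    anova = stage("stats", stats.procrustes_anova, sym.symmetric, sexes,
                  n_perm=config.anova_perms, seed=config.seed)
    metric_tests = {}
    for col in ("sharpness_ratio", "included_angle", "arc_chord_ratio",
                "arc_length", "outer_surface_area"):
        sub = table if col in ("sharpness_ratio", "included_angle",
                               "arc_chord_ratio", "arc_length") else \
            table.loc[table.index.isin(shape_ids)]
        x = sub.loc[sub.sex == "F", col].to_numpy()
        y = sub.loc[sub.sex == "M", col].to_numpy()
        r = stats.mann_whitney_u(x, y)
        metric_tests[col] = {"W": r.statistic, "p": r.p_value, "method": r.method}
    sp_corr = stats.spearman(table.sharpness_ratio.to_numpy(),
                             table.included_angle.to_numpy())

    # 6. PC1 extremes + comparative FEA ------------------------------------
    id_min, id_max = stage("select", select_extremes,
                           space.scores[:, 0], sexes, shape_ids)
    ref_id = id_min if by_id[id_min].sex == config.reference_group else id_max
    tgt_id = id_max if ref_id == id_min else id_min
    for sid in (ref_id, tgt_id):
        stage("fea-mesh", generate_volume, by_id[sid], **config.volume_resolution)
        if out:
            by_id[sid].volume_mesh.write_vtk(out / f"{sid}_volume.vtk")
    comparisons = {}
    for mode in ("unscaled", "scaled"):
        comp = stage("compare", scaling.run_comparison, by_id[ref_id], by_id[tgt_id],
                     mode=mode, order=config.fe_order,
                     with_buckling=config.with_buckling)
        comparisons[mode] = {
            "F_A_mN": comp.F_A, "F_B_mN": comp.F_B,
            "SA_A": comp.SA_A, "SA_B": comp.SA_B,
            "V_A": comp.V_A, "V_B": comp.V_B,
            "pct_differences": comp.pct_differences,
            "summaries": {f"{t}_{lmode}": s.__dict__
                          for (t, lmode), s in comp.summaries.items()},
            "U_B_adjusted": comp.U_B_adjusted,
        }
        if out:
            scaling.comparison_table(comp).to_csv(
                out / f"fe_comparison_{mode}.csv", index=False)

    pc1_means = {s: float(space.scores[sexes == s, 0].mean()) for s in np.unique(sexes)}
    import billmech

    report = StudyReport(
        config_digest=config.digest(),
        n_specimens=len(specimens),
        n_shape=len(shape_ids),
        pct_variance=[float(v) for v in space.pct_variance[:5]],
        pc1_group_means=pc1_means,
        anova_sex={"r_squared": anova.r_squared, "f": anova.f_stat,
                   "p": anova.p_value, "n_perm": anova.n_permutations},
        metric_tests=metric_tests,
        spearman_sharpness_angle={"r": sp_corr.statistic, "p": sp_corr.p_value},
        extremes={"reference": ref_id, "target": tgt_id},
        fe_comparisons=comparisons,
        provenance={"seed": config.seed, "version": billmech.__version__},
    )
    if out:
        report.to_json(out / "report.json")
        with open(out / "report.txt", "w") as fh:
            fh.write(render_report(report))
    return report


def render_report(report: StudyReport) -> str:
    """Human-readable study summary."""
    lines = [
        f"study {report.config_digest}: {report.n_specimens} specimens "
        f"({report.n_shape} in shape analysis)",
        "PC variance (%): " + ", ".join(f"{v:.2f}" for v in report.pct_variance),
        "PC1 group means: " + ", ".join(f"{k}={v:+.4f}"
                                        for k, v in report.pc1_group_means.items()),
        f"sex Procrustes ANOVA: R2={report.anova_sex['r_squared']:.3f} "
        f"p={report.anova_sex['p']:.4g} ({report.anova_sex['n_perm']} permutations)",
    ]
    for metric, r in report.metric_tests.items():
        lines.append(f"Mann-Whitney {metric}: W={r['W']:.0f} p={r['p']:.4g} ({r['method']})")
    sp = report.spearman_sharpness_angle
    lines.append(f"Spearman sharpness~angle: r={sp['r']:.3f} p={sp['p']:.4g}")
    lines.append(f"PC1 extremes: reference {report.extremes['reference']}, "
                 f"target {report.extremes['target']}")
    for mode, c in report.fe_comparisons.items():
        lines.append(f"{mode}: F_A={c['F_A_mN']:.0f} mN, F_B={c['F_B_mN']:.0f} mN")
        for lmode, pct in c["pct_differences"].items():
            diffs = ", ".join(f"{k} {v:+.1f}%" for k, v in pct.items())
            lines.append(f"  {lmode}: {diffs}")
    return "\n".join(lines) + "\n"
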