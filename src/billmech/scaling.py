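"""Comparative finite-element protocol: unscaled vs. scaled load cases.

Comparing FE results between specimens of different size requires removing
size from the loads.  Stress comparisons use loads at an identical
force:surface-area ratio,

    F_B = F_A * SA_B / SA_A,

with SA the surface area of the entire closed model.  Strain-energy
comparisons additionally adjust the target model's computed energy to the
reference size,

    U_B' = U_B * (F_A / F_B)^2 * (V_B / V_A)^volume_exponent,

with volume_exponent = 1/3 by default: under linear elasticity U scales with
F^2 and, for geometrically similar models, inversely with linear size
V^(1/3), so this is the unique exponent for which two models differing only
in scale, loaded per the force:surface-area rule, obtain identical adjusted
strain energies.  The adjustment applies to the target (scaled) model only.

The unscaled protocol instead applies empirically measured puncture forces
(defaults 200 mN to the reference/female model and 125 mN to the
target/male model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fea
from .fea import DEFAULT_MATERIALS, FEModel, PerformanceSummary
from .metrics import triangle_areas
from .synthetic import BillSpecimen

UNSCALED_FORCES_MN = {"reference": 200.0, "target": 125.0}


@dataclass
class ScalingComparison:
    reference_id: str
    target_id: str
    mode: str                      # 'scaled' or 'unscaled'
    F_A: float                     # mN applied to reference
    F_B: float                     # mN applied to target
    SA_A: float
    SA_B: float
    V_A: float
    V_B: float
    summaries: dict = field(default_factory=dict)   # (model, load_mode) -> PerformanceSummary
    U_B_adjusted: dict = field(default_factory=dict)  # load_mode -> mJ (scaled mode only)
    pct_differences: dict = field(default_factory=dict)  # load_mode -> {metric: %}


def scale_force(F_A: float, SA_A: float, SA_B: float) -> float:
    """Load for the target model at the reference force:surface-area ratio."""
    if SA_A <= 0 or SA_B <= 0:
        raise ValueError("surface areas must be positive")
    if F_A <= 0:
        raise ValueError("reference force must be positive")
    return F_A * SA_B / SA_A


def adjust_strain_energy(
    U_B: float, F_A: float, F_B: float, V_A: float, V_B: float,
    volume_exponent: float = 1.0 / 3.0,
) -> float:
    """Adjust the target model's strain energy to the reference size/force."""
    if min(F_A, F_B) <= 0:
        raise ValueError("forces must be positive")
    if min(V_A, V_B) <= 0:
        raise ValueError("volumes must be positive")
    return U_B * (F_A / F_B) ** 2 * (V_B / V_A) ** volume_exponent


def compare_performance(summary_A, summary_B) -> dict[str, float]:
    """Percentage difference of B relative to A per shared metric."""
    a = summary_A.__dict__ if hasattr(summary_A, "__dict__") else dict(summary_A)
    b = summary_B.__dict__ if hasattr(summary_B, "__dict__") else dict(summary_B)
    out = {}
    for key in a:
        va, vb = a[key], b.get(key)
        if va is None or vb is None:
            continue
        if va == 0:
            raise ValueError(f"zero reference value for metric {key!r}")
        out[key] = 100.0 * (vb - va) / va
    return out


def model_surface_area(specimen: BillSpecimen) -> float:
    """Surface area of the entire closed volume-mesh boundary (mm^2).

    This is the whole-model area used by the force-scaling rule — distinct
    from the morphometric outer-maxilla selection area.
    """
    vm = specimen.volume_mesh
    if vm is None:
        raise ValueError(f"specimen {specimen.id} has no volume mesh")
    faces = vm.boundary_faces()
    return float(triangle_areas(vm.points, faces).sum())


def run_comparison(
    specimen_A: BillSpecimen,
    specimen_B: BillSpecimen,
    mode: str = "scaled",
    load_modes: tuple[str, ...] = ("horizontal", "parallel"),
    reference_force_mN: float = UNSCALED_FORCES_MN["reference"],
    target_force_mN: float = UNSCALED_FORCES_MN["target"],
    materials: dict | None = None,
    order: int = 2,
    with_buckling: bool = True,
    volume_exponent: float = 1.0 / 3.0,
) -> ScalingComparison:
    """Full two-model comparative FE run at both stabbing angles.

    ``scaled``: the reference force is applied to A and the
    force:surface-area-matched force to B; B's strain energy is adjusted to
    the reference force:size before percentage differences are computed.
    ``unscaled``: the empirical puncture forces are applied as given.
    """
    if mode not in ("scaled", "unscaled"):
        raise ValueError("mode must be 'scaled' or 'unscaled'")
    for sp in (specimen_A, specimen_B):
        if sp.volume_mesh is None:
            raise ValueError(f"specimen {sp.id} has no volume mesh")
    materials = materials or DEFAULT_MATERIALS
    SA_A = model_surface_area(specimen_A)
    SA_B = model_surface_area(specimen_B)
    V_A = specimen_A.volume_mesh.total_volume()
    V_B = specimen_B.volume_mesh.total_volume()
    F_A = reference_force_mN
    F_B = scale_force(F_A, SA_A, SA_B) if mode == "scaled" else target_force_mN

    comp = ScalingComparison(
        reference_id=specimen_A.id, target_id=specimen_B.id, mode=mode,
        F_A=F_A, F_B=F_B, SA_A=SA_A, SA_B=SA_B, V_A=V_A, V_B=V_B,
    )
    for sp, force, tag in ((specimen_A, F_A, "A"), (specimen_B, F_B, "B")):
        model = FEModel(sp.volume_mesh, materials, order=order)
        K = fea.assemble(model)
        lu, _ = fea.factorize(model, K, model.node_set("base"))
        for lm in load_modes:
            bc = fea.make_bc(model, lm, force,
                             tip_point=sp.meta.get("tip_point"),
                             tip_tangent=sp.meta.get("tip_tangent"))
            _, summary = fea.analyze(model, bc, K=K, with_buckling=with_buckling, lu=lu)
            comp.summaries[(tag, lm)] = summary

    for lm in load_modes:
        sA = comp.summaries[("A", lm)]
        sB = comp.summaries[("B", lm)]
        if mode == "scaled":
            ub_adj = adjust_strain_energy(sB.strain_energy, F_A, F_B, V_A, V_B,
                                          volume_exponent)
            comp.U_B_adjusted[lm] = ub_adj
            sB_cmp = PerformanceSummary(
                peak_vm_98=sB.peak_vm_98, mwam_vm=sB.mwam_vm,
                strain_energy=ub_adj, buckling_load_factor=sB.buckling_load_factor,
            )
        else:
            sB_cmp = sB
        comp.pct_differences[lm] = compare_performance(sA, sB_cmp)
    return comp


def comparison_table(comp: ScalingComparison) -> pd.DataFrame:
    """Long-format report table: metric, values, percentage difference."""
    rows = []
    for lm, pct in comp.pct_differences.items():
        sA = comp.summaries[("A", lm)].__dict__
        sB = comp.summaries[("B", lm)].__dict__
        for metric, d in pct.items():
            vb = comp.U_B_adjusted.get(lm) if (metric == "strain_energy" and
                                               comp.mode == "scaled") else sB[metric]
            rows.append({
                "metric": metric, "load_mode": lm, "scaling_mode": comp.mode,
                "value_A": sA[metric], "value_B": vb, "pct_difference": d,
            })
    return pd.DataFrame(rows)
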