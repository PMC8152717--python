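"""Coronary physiology indices from pressure and absolute flow.

Given the proximal (Pa) and distal (Pd) pressures of an epicardial artery
and the absolute volumetric flow Q (mL/min) — measured, supplied, or
computed by inverting the CFD pressure–flow model — the hydraulic analogue
of Ohm's law yields the index panel that separates epicardial from
microvascular disease:

    MVR = (Pd − Pv) / Q      microvascular resistance, mmHg per (mL/min)
    SR  = (Pa − Pd) / Q      stenosis (epicardial) resistance
    FFR = Pd / Pa            at hyperaemia (resting value reported as Pd/Pa)
    CFR = Q_hyp / Q_base     coronary flow reserve
    CFR_P-D = sqrt(ΔP_hyp / ΔP_base)   pressure-derived CFR

Pv is an optional venous back-pressure (default 0); the packaged clinical
case table uses Pv = 5 mmHg for part of its cohort (see ``coroflow.io``).

The pressure-derived CFR uses the square root of the translesional
gradient ratio: across a stenosis the gradient grows roughly with the
square of flow once inertial losses dominate, so the gradient ratio
tracks the squared flow ratio. The plain gradient ratio is also exposed.

Validity limits: the method needs a translesional gradient of at least
4 mmHg to drive the simulation, which at typical aortic pressure means
FFR ≤ 0.95; panels outside these limits are computed but flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CaseRecord",
    "StatePanel",
    "PhysiologyPanel",
    "mvr",
    "sr",
    "cfr",
    "ffr_and_pdpa",
    "cfr_pressure_derived",
    "percent_delta",
    "analyze_case",
    "MIN_GRADIENT_MMHG",
    "MAX_VALIDATED_FFR",
]

#: Minimum translesional gradient (mmHg) required to drive the flow computation.
MIN_GRADIENT_MMHG = 4.0
#: Upper FFR bound of the validated range (≈ 4 mmHg gradient at Pa ~ 90 mmHg).
MAX_VALIDATED_FFR = 0.95


@dataclass(frozen=True)
class CaseRecord:
    """One patient/vessel: paired baseline and hyperaemic pressures.

    ``q_bl_mL_min``/``q_hyp_mL_min`` carry externally supplied flows (e.g. a
    published case table); when absent the flow is solved from the gradient
    and the vessel geometry. ``venous_pressure_mmHg`` is subtracted from Pd
    in the MVR calculation.
    """

    case_id: str
    artery: str = ""
    pa_bl: float = float("nan")
    pd_bl: float = float("nan")
    pa_hyp: float = float("nan")
    pd_hyp: float = float("nan")
    q_bl_mL_min: float | None = None
    q_hyp_mL_min: float | None = None
    venous_pressure_mmHg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pa_bl", "pd_bl", "pa_hyp", "pd_hyp"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be positive, got {v}")

    def gradient_flags(self) -> list[str]:
        """Flag (never silently fix) states where Pd exceeds Pa."""
        flags = []
        if self.pd_bl > self.pa_bl:
            flags.append("negative-gradient-baseline")
        if self.pd_hyp > self.pa_hyp:
            flags.append("negative-gradient-hyperaemic")
        return flags


def mvr(pd_mmHg: float, q_mL_min: float, pv_mmHg: float = 0.0) -> float:
    """Microvascular resistance (Pd − Pv)/Q in mmHg per (mL/min)."""
    if not q_mL_min > 0:
        raise ValueError("MVR requires Q > 0")
    return (pd_mmHg - pv_mmHg) / q_mL_min


def sr(pa_mmHg: float, pd_mmHg: float, q_mL_min: float) -> float:
    """Stenosis resistance (Pa − Pd)/Q in mmHg per (mL/min)."""
    if not q_mL_min > 0:
        raise ValueError("SR requires Q > 0")
    return (pa_mmHg - pd_mmHg) / q_mL_min


def cfr(q_hyp_mL_min: float, q_bl_mL_min: float) -> float:
    """Coronary flow reserve: hyperaemic over baseline flow."""
    if not q_bl_mL_min > 0:
        raise ValueError("CFR requires baseline Q > 0")
    if not q_hyp_mL_min > 0:
        raise ValueError("CFR requires hyperaemic Q > 0")
    return q_hyp_mL_min / q_bl_mL_min


def ffr_and_pdpa(pa_mmHg: float, pd_mmHg: float) -> float:
    """Distal-to-proximal pressure ratio Pd/Pa.

    The same ratio is called FFR when measured at hyperaemia and Pd/Pa at
    rest; the arithmetic is identical.
    """
    if not pa_mmHg > 0:
        raise ValueError("Pd/Pa requires Pa > 0")
    return pd_mmHg / pa_mmHg


def cfr_pressure_derived(dp_hyp_mmHg: float, dp_bl_mmHg: float,
                         form: str = "sqrt") -> float:
    """Pressure-derived CFR from the hyperaemic/baseline gradient ratio.

    ``form='sqrt'`` (default) returns sqrt(ΔP_hyp/ΔP_base), consistent with
    a near-quadratic gradient–flow relation across the stenosis;
    ``form='ratio'`` returns the plain gradient ratio.
    """
    if not dp_bl_mmHg > 0:
        raise ValueError("CFR_P-D requires a positive baseline gradient")
    if dp_hyp_mmHg < 0:
        raise ValueError("CFR_P-D requires a non-negative hyperaemic gradient")
    ratio = dp_hyp_mmHg / dp_bl_mmHg
    if form == "sqrt":
        return math.sqrt(ratio)
    if form == "ratio":
        return ratio
    raise ValueError(f"unknown CFR_P-D form {form!r}")


def percent_delta(x_base: float, x_hyp: float) -> float:
    """Baseline-to-hyperaemia change, 100·(x_hyp − x_base)/x_base."""
    if x_base == 0:
        raise ValueError("percent delta undefined for zero baseline")
    return 100.0 * (x_hyp - x_base) / x_base


@dataclass(frozen=True)
class StatePanel:
    """Indices for one physiological state (baseline or hyperaemic)."""

    state: str
    pa_mmHg: float
    pd_mmHg: float
    dp_mmHg: float
    pd_over_pa: float
    q_mL_min: float
    mvr: float
    sr: float


@dataclass(frozen=True)
class PhysiologyPanel:
    """Full per-case index panel across both states, with validity flags."""

    case_id: str
    baseline: StatePanel
    hyperaemic: StatePanel
    ffr: float
    cfr: float
    cfr_pressure_derived: float
    cfr_pressure_derived_ratio: float
    pct_delta_mvr: float
    pct_delta_sr: float
    pct_delta_q: float
    flags: tuple[str, ...] = field(default=())

    @property
    def valid(self) -> bool:
        return not self.flags

    def as_dict(self) -> dict:
        d = {"case_id": self.case_id}
        for sp in (self.baseline, self.hyperaemic):
            tag = "bl" if sp.state == "baseline" else "hyp"
            d.update({
                f"pa_{tag}": sp.pa_mmHg, f"pd_{tag}": sp.pd_mmHg,
                f"dp_{tag}": sp.dp_mmHg, f"pdpa_{tag}": sp.pd_over_pa,
                f"q_{tag}": sp.q_mL_min, f"mvr_{tag}": sp.mvr,
                f"sr_{tag}": sp.sr,
            })
        d.update({
            "ffr": self.ffr, "cfr": self.cfr,
            "cfr_pd": self.cfr_pressure_derived,
            "cfr_pd_ratio": self.cfr_pressure_derived_ratio,
            "pct_delta_mvr": self.pct_delta_mvr,
            "pct_delta_sr": self.pct_delta_sr,
            "pct_delta_q": self.pct_delta_q,
            "flags": ";".join(self.flags),
        })
        return d


def _state_panel(state: str, pa: float, pd: float, q: float, pv: float) -> StatePanel:
    return StatePanel(
        state=state, pa_mmHg=pa, pd_mmHg=pd, dp_mmHg=pa - pd,
        pd_over_pa=ffr_and_pdpa(pa, pd), q_mL_min=q,
        mvr=mvr(pd, q, pv), sr=sr(pa, pd, q),
    )


def analyze_case(record: CaseRecord, geometry=None, fluid=None,
                 settings=None) -> PhysiologyPanel:
    """Compute the full physiology panel for one case.

    Flows are taken from the record when supplied; otherwise the vessel
    geometry is required and each state's flow is computed by inverting the
    CFD pressure–flow relation against the measured gradient.
    """
    flags = record.gradient_flags()

    q_bl, q_hyp = record.q_bl_mL_min, record.q_hyp_mL_min
    if q_bl is None or q_hyp is None:
        if geometry is None:
            raise ValueError(
                "analyze_case needs either externally supplied flows or a "
                "vessel geometry to solve them from the pressure gradients")
        from .solver import FlowModel, FluidProperties, SolverSettings

        model = FlowModel(geometry, fluid or FluidProperties.blood(),
                          settings or SolverSettings())
        if "negative-gradient-baseline" in flags or \
           "negative-gradient-hyperaemic" in flags:
            raise ValueError(
                "cannot solve flow for a state with Pd > Pa; flags: "
                f"{flags}")
        if q_bl is None:
            q_bl = model.invert(record.pa_bl - record.pd_bl).Q_mL_min
        if q_hyp is None:
            q_hyp = model.invert(record.pa_hyp - record.pd_hyp).Q_mL_min

    pv = record.venous_pressure_mmHg
    base = _state_panel("baseline", record.pa_bl, record.pd_bl, q_bl, pv)
    hyp = _state_panel("hyperaemic", record.pa_hyp, record.pd_hyp, q_hyp, pv)

    if base.dp_mmHg < MIN_GRADIENT_MMHG:
        flags.append("gradient-below-4mmHg-baseline")
    if hyp.dp_mmHg < MIN_GRADIENT_MMHG:
        flags.append("gradient-below-4mmHg-hyperaemic")
    ffr_val = hyp.pd_over_pa
    if ffr_val > MAX_VALIDATED_FFR:
        flags.append("ffr-outside-validated-range")

    if base.dp_mmHg > 0 and hyp.dp_mmHg >= 0:
        cfr_pd = cfr_pressure_derived(hyp.dp_mmHg, base.dp_mmHg, "sqrt")
        cfr_pd_ratio = cfr_pressure_derived(hyp.dp_mmHg, base.dp_mmHg, "ratio")
    else:
        cfr_pd = cfr_pd_ratio = float("nan")

    return PhysiologyPanel(
        case_id=record.case_id,
        baseline=base,
        hyperaemic=hyp,
        ffr=ffr_val,
        cfr=cfr(q_hyp, q_bl),
        cfr_pressure_derived=cfr_pd,
        cfr_pressure_derived_ratio=cfr_pd_ratio,
        pct_delta_mvr=percent_delta(base.mvr, hyp.mvr),
        pct_delta_sr=percent_delta(base.sr, hyp.sr),
        pct_delta_q=percent_delta(q_bl, q_hyp),
        flags=tuple(flags),
    )
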