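"""Non-imaging assay computations for renal epithelial monolayer studies.

Covers the Mito Stress Test (phased oxygen-consumption-rate traces ->
respiration parameters), 2^-ddCt relative qPCR abundance, ATP normalized
to protein via a luminescence standard curve, the GSH/GSSG redox ratio,
and per-tubule respiratory-chain-complex Z-scores for biopsy
immunofluorescence normalized to VDAC1 (mitochondrial mass).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHASE_ORDER",
    "OCRTrace",
    "MitoStressParams",
    "QpcrMeasurement",
    "AtpAssay",
    "mito_stress_params",
    "ddct_ratio",
    "atp_per_protein",
    "gsh_gssg_ratio",
    "biopsy_zscores",
]

#: Injection phases of the Mito Stress Test, in protocol order:
#: baseline, then oligomycin (ATP-synthase inhibitor), then FCCP
#: (uncoupler), then rotenone + antimycin A (complex I/III inhibitors).
PHASE_ORDER = ("basal", "post_oligomycin", "post_fccp", "post_rot_aa")


class OCRTrace:
    """One replicate's oxygen consumption rate (OCR) trace.

    Ordered measurement cycles with columns ``time_min``, ``ocr``
    (pmol O2/min) and ``phase`` (one of :data:`PHASE_ORDER`). The assay
    protocol records three cycles per phase, but any positive number of
    cycles per phase is accepted.
    """

    def __init__(self, cycles: pd.DataFrame, replicate: str | int = 0):
        required = {"time_min", "ocr", "phase"}
        missing = required - set(cycles.columns)
        if missing:
            raise ValueError(f"OCR trace missing columns {sorted(missing)}")
        cycles = cycles.sort_values("time_min", kind="stable").reset_index(drop=True)
        bad = set(cycles["phase"]) - set(PHASE_ORDER)
        if bad:
            raise ValueError(f"unknown phases {sorted(bad)}")
        # phases must appear as contiguous blocks in protocol order
        seen = [p for p, _ in itertools.groupby(cycles["phase"])]
        if seen != [p for p in PHASE_ORDER if p in seen]:
            raise ValueError(f"phases out of protocol order: {seen}")
        self.cycles = cycles
        self.replicate = replicate

    @classmethod
    def from_csv(cls, path, replicate_column: str = "replicate") -> "list[OCRTrace]":
        """Load one trace per replicate from a long-format CSV."""
        df = pd.read_csv(path)
        if replicate_column in df.columns:
            return [
                cls(g.drop(columns=[replicate_column]), replicate=r)
                for r, g in df.groupby(replicate_column, sort=True)
            ]
        return [cls(df)]

    def phase_values(self, phase: str) -> np.ndarray:
        return self.cycles.loc[self.cycles["phase"] == phase, "ocr"].to_numpy(float)


@dataclass(frozen=True)
class MitoStressParams:
    """Derived respiration parameters, all in pmol O2/min (spare_pct in %)."""

    non_mito: float
    basal_resp: float
    atp_linked: float
    proton_leak: float
    maximal: float
    spare: float
    spare_pct: float  # NaN when basal respiration is not positive

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def mito_stress_params(trace: OCRTrace, selector: str = "vendor") -> MitoStressParams:
    """Partition an OCR trace into respiration components.

    With ``selector='vendor'`` (the convention of the plate-assay vendor):
    non-mitochondrial = last rotenone/antimycin-A cycle; basal uses the
    last baseline cycle; ATP-linked uses the minimum post-oligomycin
    cycle; maximal uses the maximum post-FCCP cycle. With
    ``selector='phase_mean'`` every extremum/last is replaced by the
    phase mean.

    Identities hold by construction:
    ``basal_resp = atp_linked + proton_leak`` and
    ``spare = maximal - basal_resp``.
    """
    if selector not in ("vendor", "phase_mean"):
        raise ValueError(f"unknown selector {selector!r}")
    vals = {}
    for phase in PHASE_ORDER:
        v = trace.phase_values(phase)
        if v.size == 0:
            raise ValueError(f"missing phase {phase!r} in OCR trace")
        vals[phase] = v

    if selector == "vendor":
        non_mito = float(vals["post_rot_aa"][-1])
        basal_raw = float(vals["basal"][-1])
        oligo = float(vals["post_oligomycin"].min())
        fccp = float(vals["post_fccp"].max())
    else:
        non_mito = float(vals["post_rot_aa"].mean())
        basal_raw = float(vals["basal"].mean())
        oligo = float(vals["post_oligomycin"].mean())
        fccp = float(vals["post_fccp"].mean())

    basal_resp = basal_raw - non_mito
    atp_linked = basal_raw - oligo
    proton_leak = oligo - non_mito
    maximal = fccp - non_mito
    spare = maximal - basal_resp
    if basal_resp > 0:
        spare_pct = 100.0 * maximal / basal_resp
    else:
        warnings.warn(
            "basal respiration is not positive; spare_pct undefined",
            RuntimeWarning, stacklevel=2,
        )
        spare_pct = float("nan")
    return MitoStressParams(
        non_mito=non_mito, basal_resp=basal_resp, atp_linked=atp_linked,
        proton_leak=proton_leak, maximal=maximal, spare=spare, spare_pct=spare_pct,
    )


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct quadruple for relative quantification of target vs reference gene."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float
    target_gene: str = "target"
    reference_gene: str = "reference"

    def __post_init__(self) -> None:
        for name, v in (
            ("ct_target_treated", self.ct_target_treated),
            ("ct_reference_treated", self.ct_reference_treated),
            ("ct_target_control", self.ct_target_control),
            ("ct_reference_control", self.ct_reference_control),
        ):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")


def ddct_ratio(m: QpcrMeasurement) -> float:
    """Fold change 2^-ddCt of target abundance, treated relative to control."""
    dct_treated = m.ct_target_treated - m.ct_reference_treated
    dct_control = m.ct_target_control - m.ct_reference_control
    ddct = dct_treated - dct_control
    return float(2.0 ** (-ddct))


@dataclass
class AtpAssay:
    """Luminescence ATP assay with a standard curve and protein normalization."""

    sample_luminescence: float
    standards: list[tuple[float, float]]  # (ATP amount, luminescence)
    protein_mg: float
    extrapolated: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        if self.protein_mg <= 0:
            raise ValueError("protein_mg must be positive")
        amounts = [a for a, _ in self.standards]
        if len(set(amounts)) < 2:
            raise ValueError("need >= 2 standard points with distinct ATP amounts")


def atp_per_protein(assay: AtpAssay) -> float:
    """ATP per mg protein, via least-squares inversion of the standard curve."""
    amounts = np.array([a for a, _ in assay.standards], dtype=float)
    lums = np.array([l for _, l in assay.standards], dtype=float)
    order = np.argsort(amounts, kind="stable")
    sorted_lums = lums[order][np.concatenate(([True], np.diff(amounts[order]) > 0))]
    if not (np.all(np.diff(sorted_lums) > 0) or np.all(np.diff(sorted_lums) < 0)):
        raise ValueError("standard curve must be strictly monotone in luminescence")
    slope, intercept = np.polyfit(amounts, lums, 1)
    lum = assay.sample_luminescence
    lo, hi = lums.min(), lums.max()
    if not (lo <= lum <= hi):
        assay.extrapolated = True
        warnings.warn(
            f"sample luminescence {lum} outside standard range [{lo}, {hi}]; "
            "extrapolating", RuntimeWarning, stacklevel=2,
        )
    atp = (lum - intercept) / slope
    return float(atp / assay.protein_mg)


def gsh_gssg_ratio(gsh_abundance: float, gssg_abundance: float) -> float:
    """Reduced-to-oxidized glutathione ratio; NaN when GSSG is zero."""
    if gsh_abundance < 0 or gssg_abundance < 0:
        raise ValueError("abundances must be non-negative")
    if gssg_abundance == 0:
        warnings.warn("GSSG abundance is zero; ratio undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(gsh_abundance / gssg_abundance)


def biopsy_zscores(
    intensities: pd.DataFrame,
    background: pd.DataFrame,
    reference_marker: str = "VDAC1",
) -> pd.DataFrame:
    """Per-tubule Z-scores of complex-marker intensity relative to controls.

    ``intensities``: long-format table with columns ``tubule_id``,
    ``group`` ('case' or 'control'), ``marker`` and ``raw_od`` (raw
    optical density). ``background``: columns ``marker`` and ``mean_od``
    (mean no-primary-control optical density per fluorophore).

    Pipeline: subtract the background mean per fluorophore (clipping at
    zero), normalize each marker by the same tubule's corrected
    ``reference_marker`` intensity, then express each normalized value as
    a Z-score against the mean and sample (n-1) SD of the control
    tubules for that marker. Tubules whose corrected reference intensity
    is not positive are excluded and flagged.

    Returns a table with columns ``tubule_id, group, marker, corrected,
    normalized, z, excluded``.
    """
    req = {"tubule_id", "group", "marker", "raw_od"}
    if not req <= set(intensities.columns):
        raise ValueError(f"intensity table needs columns {sorted(req)}")
    bg = background.set_index("marker")["mean_od"]
    df = intensities.copy()
    df["corrected"] = (
        df["raw_od"] - df["marker"].map(bg).fillna(0.0)
    ).clip(lower=0.0)

    ref = (
        df[df["marker"] == reference_marker]
        .set_index("tubule_id")["corrected"]
    )
    if ref.empty:
        raise ValueError(f"no {reference_marker!r} measurements present")
    df["ref_corrected"] = df["tubule_id"].map(ref)
    df["excluded"] = ~(df["ref_corrected"] > 0)
    df["normalized"] = np.where(
        df["excluded"], np.nan, df["corrected"] / df["ref_corrected"]
    )

    out = df[df["marker"] != reference_marker].copy()
    controls = out[(out["group"] == "control") & ~out["excluded"]]
    if controls.empty:
        raise ValueError("control group is empty after exclusions")
    stats = controls.groupby("marker")["normalized"].agg(["mean", "std"])
    if (stats["std"].fillna(0.0) == 0.0).any():
        zero = stats.index[stats["std"].fillna(0.0) == 0.0].tolist()
        raise ValueError(f"control SD is zero for markers {zero}")
    out["z"] = (
        out["normalized"] - out["marker"].map(stats["mean"])
    ) / out["marker"].map(stats["std"])
    cols = ["tubule_id", "group", "marker", "corrected", "normalized", "z", "excluded"]
    return out.loc[:, cols].reset_index(drop=True)
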