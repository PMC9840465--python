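"""Targeted metabolite quantification from centroided MS1 peak lists.

Workflow: molecular formula -> monoisotopic mass -> [M-H]- m/z -> ppm
extraction window -> extracted-ion chromatogram (XIC) -> peak area.

Negative-mode deprotonation is the only adduct supported; the m/z of the
ion is the neutral monoisotopic mass minus the mass of a proton
(1.007276 Da, electron mass folded into this convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "IonTarget",
    "SpectrumSeries",
    "XIC",
    "monoisotopic_mass",
    "deprotonated_mz",
    "ppm_window",
    "extract_xic",
    "integrate_area",
    "quantify_targets",
]

#: Monoisotopic masses (Da) of the lightest stable isotope of each element.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

#: Mass of a proton in Da, as used for the [M-H]- adduct.
PROTON_MASS = 1.007276

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count mapping, e.g. tenofovir C9H14N5O4P."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts or all(n == 0 for n in self.counts.values()):
            raise ValueError("formula must contain at least one atom")
        for el, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for element {el!r}")

    @classmethod
    def from_string(cls, s: str) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``'C9H14N5O4P'``."""
        s = s.strip()
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(s):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {s!r} at {s[pos:]!r}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(s) or not counts:
            raise ValueError(f"cannot parse formula {s!r}")
        return cls(counts)

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self.counts.items() if n
        )


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Neutral monoisotopic mass in Da (sum of lightest-isotope masses)."""
    if isinstance(formula, str):
        formula = MolecularFormula.from_string(formula)
    mass = 0.0
    for el, n in formula.counts.items():
        try:
            mass += n * MONOISOTOPIC_MASS[el]
        except KeyError:
            raise ValueError(f"unknown element {el!r} in formula") from None
    return mass


def deprotonated_mz(mass: float) -> float:
    """m/z of the [M-H]- ion of a neutral of the given monoisotopic mass."""
    if mass <= PROTON_MASS:
        raise ValueError(f"mass {mass} Da is not above the proton mass")
    return mass - PROTON_MASS


def ppm_window(mz: float, ppm: float) -> tuple[float, float]:
    """Symmetric relative m/z window ``(mz*(1-ppm*1e-6), mz*(1+ppm*1e-6))``."""
    if mz <= 0:
        raise ValueError("mz must be positive")
    if ppm <= 0:
        raise ValueError("ppm must be positive")
    return mz * (1.0 - ppm * 1e-6), mz * (1.0 + ppm * 1e-6)


@dataclass(frozen=True)
class IonTarget:
    """A named ion to be extracted within a ppm tolerance window.

    Only the deprotonated [M-H]- adduct is supported.
    """

    name: str
    formula: MolecularFormula
    theoretical_mz: float
    adduct: str = "deprotonated"
    ppm_tolerance: float = 3.0

    def __post_init__(self) -> None:
        if self.adduct != "deprotonated":
            raise ValueError(f"unsupported adduct {self.adduct!r}")
        if self.theoretical_mz <= 0:
            raise ValueError("theoretical_mz must be positive")
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be positive")

    @classmethod
    def from_formula(
        cls, name: str, formula: MolecularFormula | str, ppm_tolerance: float = 3.0
    ) -> "IonTarget":
        if isinstance(formula, str):
            formula = MolecularFormula.from_string(formula)
        mz = deprotonated_mz(monoisotopic_mass(formula))
        return cls(name=name, formula=formula, theoretical_mz=mz,
                   ppm_tolerance=ppm_tolerance)

    @property
    def window(self) -> tuple[float, float]:
        return ppm_window(self.theoretical_mz, self.ppm_tolerance)


class SpectrumSeries:
    """RT-sorted centroided MS1 peak list: columns rt_min, mz, intensity."""

    def __init__(self, peaks: pd.DataFrame):
        required = {"rt_min", "mz", "intensity"}
        missing = required - set(peaks.columns)
        if missing:
            raise ValueError(f"peak list missing columns {sorted(missing)}")
        peaks = peaks.loc[:, ["rt_min", "mz", "intensity"]].astype(float)
        if (peaks["intensity"] < 0).any():
            raise ValueError("intensities must be non-negative")
        self.peaks = peaks.sort_values("rt_min", kind="stable").reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "SpectrumSeries":
        return cls(pd.read_csv(path))

    @classmethod
    def from_mzml(cls, path) -> "SpectrumSeries":
        """Read centroided MS1 spectra from an mzML file (requires pyteomics)."""
        from pyteomics import mzml  # optional dependency

        rows = []
        with mzml.MzML(str(path)) as reader:
            for spec in reader:
                if spec.get("ms level", 1) != 1:
                    continue
                rt = spec["scanList"]["scan"][0]["scan start time"]
                for mz_v, inten in zip(spec["m/z array"], spec["intensity array"]):
                    rows.append((float(rt), float(mz_v), float(inten)))
        return cls(pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"]))

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class XIC:
    """Extracted-ion chromatogram: summed in-window intensity per RT."""

    rt_min: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt_min = np.asarray(self.rt_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt_min.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")

    def __len__(self) -> int:
        return len(self.rt_min)


def extract_xic(series: SpectrumSeries, target: IonTarget) -> XIC:
    """Sum peak intensities inside the target's half-open m/z window [lo, hi).

    Every distinct retention time in the series appears in the XIC; times
    with no in-window peak contribute zero, so the chromatogram has a
    well-defined baseline even for sparse ions.
    """
    df = series.peaks
    rts = np.unique(df["rt_min"].to_numpy())
    if rts.size == 0:
        return XIC(rt_min=np.empty(0), intensity=np.empty(0))
    lo, hi = target.window
    mz = df["mz"].to_numpy()
    in_win = (mz >= lo) & (mz < hi)
    sums = (
        df.loc[in_win]
        .groupby("rt_min", sort=True)["intensity"]
        .sum()
        .reindex(rts, fill_value=0.0)
    )
    return XIC(rt_min=rts, intensity=sums.to_numpy())


def integrate_area(
    xic: XIC, baseline: str = "zero"
) -> tuple[float, float]:
    """Trapezoidal area of the peak around the global apex.

    Peak bounds are the contiguous run of samples strictly above the
    baseline containing the apex. ``baseline='zero'`` integrates above
    zero; ``'linear_endpoints'`` first subtracts the straight line through
    the first and last XIC samples.

    Returns ``(area, apex_rt)``; an all-zero chromatogram yields area 0
    with ``apex_rt = nan``.
    """
    if baseline not in ("zero", "linear_endpoints"):
        raise ValueError(f"unknown baseline mode {baseline!r}")
    if len(xic) < 3:
        raise ValueError("XIC must contain at least 3 points")
    rt, y = xic.rt_min, xic.intensity.astype(float)
    if baseline == "linear_endpoints":
        base = np.interp(rt, [rt[0], rt[-1]], [y[0], y[-1]])
        y = y - base
    if not np.any(y > 0):
        return 0.0, float("nan")
    apex = int(np.argmax(y))
    lo = apex
    while lo > 0 and y[lo - 1] > 0:
        lo -= 1
    hi = apex
    while hi < len(y) - 1 and y[hi + 1] > 0:
        hi += 1
    area = float(np.trapezoid(y[lo : hi + 1], rt[lo : hi + 1]))
    return area, float(rt[apex])


def quantify_targets(
    series: SpectrumSeries,
    targets: list[IonTarget],
    baseline: str = "zero",
) -> pd.DataFrame:
    """Quantify each target: columns name, theoretical_mz, apex_rt, area."""
    rows = []
    for t in targets:
        xic = extract_xic(series, t)
        if len(xic) >= 3:
            area, apex_rt = integrate_area(xic, baseline=baseline)
        else:
            area, apex_rt = 0.0, float("nan")
        rows.append(
            {"name": t.name, "theoretical_mz": t.theoretical_mz,
             "apex_rt": apex_rt, "area": area}
        )
    return pd.DataFrame(rows, columns=["name", "theoretical_mz", "apex_rt", "area"])


def read_targets_csv(path) -> list[IonTarget]:
    """Targets file: columns name, formula, optional ppm (default 3)."""
    df = pd.read_csv(path)
    targets = []
    for _, row in df.iterrows():
        ppm = float(row["ppm"]) if "ppm" in df.columns and pd.notna(row.get("ppm")) else 3.0
        targets.append(IonTarget.from_formula(str(row["name"]), str(row["formula"]), ppm))
    return targets
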