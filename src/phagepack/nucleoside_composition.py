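"""Nucleoside composition from HPLC peak areas and thymidine substitution.

A nucleoside digest of genomic material is separated by HPLC and each
nucleoside quantified against an equimolar (50 uM) standard mixture: the
ratio sample_area / standard_area cancels the per-nucleoside detector
response and is proportional to the molar amount.  Percentages are
normalized separately within the deoxyribonucleoside (DNA) and
ribonucleoside (RNA) classes, base-pairing consistency (dA:T, dC:dG) is
checked, and a deficit of thymidine relative to the genome-predicted
percentage is converted into an estimate of the fraction of thymidines
carrying a hypermodification (which removes them from the T peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEOXY = ("dA", "dG", "dC", "T")
RIBO = ("A", "C", "G", "U")
STANDARD_CONC_UM = 50.0


class CompositionError(ValueError):
    """Raised for incomplete or uncalibrated peak-area tables."""


def read_areas(path) -> pd.DataFrame:
    """Read a peak-area table (columns: nucleoside, class, sample_area, standard_area)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"nucleoside", "class", "sample_area", "standard_area"}
    missing = required - set(df.columns)
    if missing:
        raise CompositionError(f"area table missing columns: {sorted(missing)}")
    return df


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if df["nucleoside"].duplicated().any():
        dupes = df.loc[df["nucleoside"].duplicated(), "nucleoside"].tolist()
        raise CompositionError(f"duplicate nucleoside rows: {dupes}")
    if (df["standard_area"] <= 0).any():
        raise CompositionError("standard_area must be positive (calibration error)")
    if (df["sample_area"] < 0).any():
        raise CompositionError("sample_area must be non-negative")
    deoxy = set(df.loc[df["class"] == "deoxy", "nucleoside"])
    missing = set(DEOXY) - deoxy
    if missing:
        raise CompositionError(f"incomplete table, missing deoxynucleosides: {sorted(missing)}")
    return df


@dataclass
class CompositionResult:
    """Molar percentages per class with pairing diagnostics."""

    percent: dict[str, float]  # nucleoside -> % within its class
    class_totals: dict[str, float]  # class -> sum of percentages (~100)
    pairing_ratios: tuple[float, float]  # (T/dA, dC/dG)

    def table(self) -> pd.DataFrame:
        rows = [
            {"nucleoside": n, "percent": round(p, 1)} for n, p in self.percent.items()
        ]
        return pd.DataFrame(rows)


def composition_from_areas(table: pd.DataFrame) -> CompositionResult:
    """Molar nucleoside percentages from single-point calibrated peak areas.

    amount_i = sample_area_i / standard_area_i (equal-concentration standard
    mix), then percent_i = 100 * amount_i / sum over the nucleoside's class.
    DNA and RNA classes are normalized independently.
    """
    df = _validate(table)
    df = df.assign(amount=df["sample_area"] / df["standard_area"])
    percent: dict[str, float] = {}
    class_totals: dict[str, float] = {}
    for cls, grp in df.groupby("class", sort=False):
        total = grp["amount"].sum()
        if total <= 0:
            raise CompositionError(f"no signal in class {cls!r}")
        for _, row in grp.iterrows():
            percent[row["nucleoside"]] = 100.0 * row["amount"] / total
        class_totals[cls] = sum(percent[n] for n in grp["nucleoside"])
    ratios = (
        percent["T"] / percent["dA"] if percent["dA"] > 0 else float("inf"),
        percent["dC"] / percent["dG"] if percent["dG"] > 0 else float("inf"),
    )
    return CompositionResult(percent=percent, class_totals=class_totals, pairing_ratios=ratios)


def pairing_check(result: CompositionResult, tolerance: float = 0.25) -> list[str]:
    """Watson-Crick consistency flags for the deoxy percentages.

    In duplex DNA the molar amounts should satisfy dA == T and dC == dG.
    Returns ``["T_deficit"]`` when T/dA < 1 - tolerance and/or
    ``["GC_imbalance"]`` when |dC - dG| exceeds ``tolerance`` of their mean.
    """
    p = result.percent
    flags = []
    if p["dA"] > 0 and p["T"] / p["dA"] < 1 - tolerance:
        flags.append("T_deficit")
    gc_mean = (p["dC"] + p["dG"]) / 2
    if gc_mean > 0 and abs(p["dC"] - p["dG"]) / gc_mean > tolerance:
        flags.append("GC_imbalance")
    return flags


@dataclass
class SubstitutionEstimate:
    """Fraction of thymidines inferred to carry the hypermodification."""

    expected_T_percent: float
    observed_T_percent: float
    fraction_modified: float  # in [0, 1]

    @property
    def percent_modified(self) -> int:
        """Substitution as a whole-number percentage for display."""
        return round(100 * self.fraction_modified)


def substitution_fraction(
    expected_T_percent: float, observed_T_percent: float
) -> SubstitutionEstimate:
    """Estimate the modified-thymidine fraction from the T deficit.

    Modified thymidine leaves the T peak (it elutes elsewhere), so the
    observed T percentage under-reads the genome-predicted one and
    fraction = 1 - observed/expected, clamped to [0, 1].
    """
    if expected_T_percent <= 0:
        raise ValueError("expected_T_percent must be positive")
    if observed_T_percent < 0:
        raise ValueError("observed_T_percent must be non-negative")
    frac = 1.0 - observed_T_percent / expected_T_percent
    frac = min(1.0, max(0.0, frac))
    return SubstitutionEstimate(
        expected_T_percent=expected_T_percent,
        observed_T_percent=observed_T_percent,
        fraction_modified=frac,
    )
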