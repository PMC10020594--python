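"""GC-MS terpene quantification and normalization.

Integrated peak areas are corrected for the internal standard (benzyl
acetate spiked into the hexane extract), the sample dilution and the
injected sample volume, then normalised per mg fresh leaf weight or per
collected trichome gland.  Normalised areas become ng quantities through a
calibration slope (response factor) against an authentic standard;
β-caryophyllene serves for 7-epizingiberene and its derivatives.

Plants are classified high/low against a parental reference (mean ± 1.96·sd/√n
of the wild-parent replicates), levels are binned into parental-sd-wide
histogram bins with an isolated zero bin, and the fold-change /
percent-reduction summaries used in reporting are provided as small
well-specified helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakRecord",
    "SampleMeta",
    "ResponseFactor",
    "ParentalReference",
    "normalize_peak",
    "normalize_table",
    "quantify",
    "quantify_table",
    "parental_reference",
    "classify_high_low",
    "bin_levels",
    "fold_change",
    "percent_reduction",
    "format_fold",
    "round_half_away",
    "sum_by_localization",
    "DEFAULT_LOCALIZATION",
    "INTERNAL_STANDARD_NG_PER_UL",
]

#: nominal internal-standard concentration spiked into extracts (benzyl acetate)
INTERNAL_STANDARD_NG_PER_UL = 0.5

#: sub-cellular localisation of the synthase making each compound class
DEFAULT_LOCALIZATION: dict[str, str] = {
    "7-epizingiberene": "plastidial",
    "9-hydroxy-zingiberene": "plastidial",
    "9-hydroxy-10,11-epoxyzingiberene": "plastidial",
    "R-curcumene": "plastidial",
    "alpha-santalene": "plastidial",
    "alpha-bergamotene": "plastidial",
    "beta-bergamotene": "plastidial",
    "2-carene": "plastidial",
    "alpha-phellandrene": "plastidial",
    "beta-phellandrene": "plastidial",
    "D-limonene": "plastidial",
    "terpinolene": "plastidial",
    "beta-caryophyllene": "cytosolic",
    "alpha-humulene": "cytosolic",
    "germacrene": "cytosolic",
}


@dataclass(frozen=True)
class PeakRecord:
    """One integrated GC-MS peak with its internal-standard peak."""

    sample_id: str
    compound: str
    peak_area: float
    is_area: float

    def __post_init__(self) -> None:
        if self.is_area <= 0:
            raise ValueError("internal-standard area must be > 0")
        if self.peak_area < 0:
            raise ValueError("peak area must be ≥ 0")


@dataclass(frozen=True)
class SampleMeta:
    """Sample context needed to normalise its peaks.

    ``basis`` selects the denominator: ``"fresh_weight"`` (leaf wash, mg
    fresh weight) or ``"glands"`` (isolated type-VI heads, count).
    """

    sample_id: str
    basis: str
    extraction_volume_ul: float
    injection_volume_ul: float
    dilution: float = 1.0
    fresh_weight_mg: float | None = None
    n_glands: int | None = None

    def __post_init__(self) -> None:
        if self.basis not in ("fresh_weight", "glands"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.extraction_volume_ul <= 0 or self.injection_volume_ul <= 0:
            raise ValueError("volumes must be > 0")
        if self.dilution < 1:
            raise ValueError("dilution factor must be ≥ 1")
        if self.basis == "fresh_weight":
            if self.fresh_weight_mg is None or self.fresh_weight_mg <= 0:
                raise ValueError("fresh_weight basis requires fresh_weight_mg > 0")
        else:
            if self.n_glands is None or self.n_glands <= 0:
                raise ValueError("glands basis requires n_glands > 0")

    @property
    def denominator(self) -> float:
        return (
            self.fresh_weight_mg
            if self.basis == "fresh_weight"
            else float(self.n_glands)
        )


@dataclass(frozen=True)
class ResponseFactor:
    """Calibration slope against an authentic standard (ng per unit area)."""

    compound: str
    standard_compound: str
    ng_per_unit_area: float

    def __post_init__(self) -> None:
        if self.ng_per_unit_area <= 0:
            raise ValueError("calibration slope must be > 0")


@dataclass(frozen=True)
class ParentalReference:
    """Parental replicate summary: mean ± 1.96·sd/√n."""

    mean: float
    sd: float
    n: int
    ci_low: float
    ci_high: float


def normalize_peak(rec: PeakRecord, meta: SampleMeta) -> float:
    """Internal-standard-corrected, volume/dilution-corrected area per unit basis.

    ``(peak_area / is_area) * dilution * (extraction_volume / injection_volume)
    / denominator`` with the denominator being mg fresh weight or gland count.
    Linear in ``peak_area``.
    """
    if rec.sample_id != meta.sample_id:
        raise ValueError(
            f"metadata sample {meta.sample_id!r} does not match peak "
            f"sample {rec.sample_id!r}"
        )
    return (
        (rec.peak_area / rec.is_area)
        * meta.dilution
        * (meta.extraction_volume_ul / meta.injection_volume_ul)
        / meta.denominator
    )


def normalize_table(
    peaks: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Vectorised :func:`normalize_peak` over tidy peak/metadata tables.

    ``peaks`` needs columns ``sample_id, compound, peak_area, is_area``;
    ``meta`` the :class:`SampleMeta` columns.  Returns the peak table plus
    ``basis`` and ``normalized_area`` columns.
    """
    missing = set(peaks["sample_id"]) - set(meta["sample_id"])
    if missing:
        raise ValueError(f"no metadata for samples: {sorted(missing)}")
    merged = peaks.merge(meta, on="sample_id", how="left", validate="m:1")
    if (merged["is_area"] <= 0).any():
        raise ValueError("internal-standard area must be > 0")
    denom = np.where(
        merged["basis"] == "fresh_weight",
        merged.get("fresh_weight_mg", np.nan),
        merged.get("n_glands", np.nan),
    ).astype(float)
    if np.isnan(denom).any() or (denom <= 0).any():
        raise ValueError("missing or non-positive normalisation denominator")
    merged["normalized_area"] = (
        (merged["peak_area"] / merged["is_area"])
        * merged["dilution"]
        * (merged["extraction_volume_ul"] / merged["injection_volume_ul"])
        / denom
    )
    return merged[
        ["sample_id", "compound", "basis", "normalized_area"]
    ].copy()


def quantify(normalized_area: float, rf: ResponseFactor) -> float:
    """ng per unit basis from a normalised area and a calibration slope."""
    return normalized_area * rf.ng_per_unit_area


def quantify_table(
    normalized: pd.DataFrame, rfs: Mapping[str, ResponseFactor]
) -> pd.DataFrame:
    """Apply response factors per compound.

    Compounds without a response factor keep their normalised area in the
    quantity column and are flagged ``semi-quantitative`` rather than
    dropped; calibrated compounds are flagged ``quantified``.
    """
    out = normalized.copy()
    slopes = out["compound"].map(
        {c: rf.ng_per_unit_area for c, rf in rfs.items()}
    )
    out["quant_status"] = np.where(
        slopes.notna(), "quantified", "semi-quantitative"
    )
    out["quantity"] = out["normalized_area"] * slopes.fillna(1.0)
    unit = np.where(
        out["basis"] == "fresh_weight", "ng_per_mg_fw", "ng_per_gland"
    )
    out["unit"] = np.where(
        out["quant_status"] == "quantified", unit, "is_ratio_area"
    )
    return out


def parental_reference(values: Sequence[float]) -> ParentalReference:
    """Mean, sample sd and 95% CI (mean ± 1.96·sd/√n) of parental replicates."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need ≥2 parental replicates")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = 1.96 * sd / math.sqrt(n)
    return ParentalReference(mean, sd, n, mean - half, mean + half)


def classify_high_low(
    value: float, ref: ParentalReference, rule: str = "ci_low"
) -> str:
    """Call a plant ``"high"`` when its level reaches the parental reference.

    Default rule: high iff value ≥ lower bound of the parental 95% CI
    ("parental levels or higher").  ``rule="mean"`` compares to the parental
    mean instead.
    """
    if rule == "ci_low":
        cut = ref.ci_low
    elif rule == "mean":
        cut = ref.mean
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return "high" if value >= cut else "low"


def bin_levels(
    values: Sequence[float],
    parental_sd: float,
    detection_limit: float = 0.0,
) -> pd.DataFrame:
    """Histogram with parental-sd-wide bins and an isolated zero bin.

    Bin 0 holds exact zeros (values at or below ``detection_limit`` are
    zeroed first); a positive value v falls in bin ``ceil(v/sd)``
    (left-open, right-closed).  Returns a frame with ``bin``, ``lower``,
    ``upper`` and ``count``; counts sum to ``len(values)``.
    """
    if parental_sd <= 0:
        raise ValueError("parental sd must be > 0")
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("levels must be non-negative")
    values = np.where(values <= detection_limit, 0.0, values)
    idx = np.where(
        values == 0.0, 0, np.ceil(values / parental_sd).astype(int)
    )
    n_bins = int(idx.max()) + 1 if idx.size else 1
    counts = np.bincount(idx, minlength=n_bins)
    bins = np.arange(n_bins)
    lower = np.where(bins == 0, 0.0, (bins - 1) * parental_sd)
    upper = bins * parental_sd
    return pd.DataFrame(
        {"bin": bins, "lower": lower, "upper": upper, "count": counts}
    )


def fold_change(a: float, b: float) -> float:
    """Ratio a/b (e.g. parental 17.7 ng/gland over cultivar 0.51 → ~35)."""
    if b <= 0:
        raise ValueError("denominator must be > 0")
    return a / b


def percent_reduction(control: float, treated: float) -> float:
    """Percent reduction 100·(control − treated)/control.

    Negative (an increase) is allowed and simply returned negative; callers
    decide whether to flag it.
    """
    if control <= 0:
        raise ValueError("control level must be > 0")
    return 100.0 * (control - treated) / control


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for reported
    percentages, where 62.5 prints as 63)."""
    scale = 10.0**ndigits
    r = math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale
    return r if ndigits > 0 else int(r)


def format_fold(fc: float) -> str:
    """Display rule for fold changes: integer when ≥10, else 1 dp."""
    if fc >= 10:
        return f"~{int(round_half_away(fc))}"
    return f"~{round_half_away(fc, 1):g}"


def sum_by_localization(
    quantified: pd.DataFrame,
    localization: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample plastidial and cytosolic terpene totals.

    ``quantified`` needs ``sample_id, compound, quantity``.  Compounds absent
    from the map are excluded from the totals and returned in the second
    element, never silently included.
    """
    if localization is None:
        localization = DEFAULT_LOCALIZATION
    loc = quantified["compound"].map(dict(localization))
    unmapped = sorted(quantified.loc[loc.isna(), "compound"].unique())
    mapped = quantified.loc[loc.notna()].assign(localization=loc.dropna())
    totals = (
        mapped.pivot_table(
            index="sample_id",
            columns="localization",
            values="quantity",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=["plastidial", "cytosolic"], fill_value=0.0)
        .reset_index()
    )
    totals.columns.name = None
    return totals, unmapped


def write_quantified_csv(table: pd.DataFrame, path) -> None:
    """Write a quantified table at full precision."""
    table.to_csv(path, index=False)


def read_quantified_csv(path) -> pd.DataFrame:
    """Read back a quantified table bit-identically.

    Uses the exact (round-trip) float parser: the default fast parser can
    be one ulp off, which breaks regeneration of byte-identical reports.
    """
    return pd.read_csv(path, float_precision="round_trip")


def log2_transform(
    table: pd.DataFrame, column: str, offset: float = 0.0
) -> pd.DataFrame:
    """Log2-transform a quantity column (as done before ANOVA in reporting)."""
    out = table.copy()
    vals = out[column] + offset
    if (vals <= 0).any():
        raise ValueError("log2 transform requires positive values (use offset)")
    out[column + "_log2"] = np.log2(vals)
    return out
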