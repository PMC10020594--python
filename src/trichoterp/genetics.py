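"""Multi-locus Mendelian segregation models for an F2 (selfed-F1) population.

A qualitative "high" phenotype is modelled as the conjunction of per-locus
requirements: a *recessive* locus requires the plant to be homozygous for the
wild-parent allele, a *dominant* locus requires at least one wild-parent
allele.  Under independent assortment from a fully heterozygous F1, each
recessive locus is satisfied with probability 1/4 and each dominant locus
with probability 3/4, so the expected F2 fraction of high plants is the
product over loci.

Candidate gene models are ranked against observed high/low counts with the
Pearson chi-square goodness-of-fit test (df = 1, no continuity correction by
default).  The ranking is exposed statsmodels-style through
:class:`SegregationModelSelection` / :class:`SegregationResults`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Mode",
    "LocusRequirement",
    "GeneticModel",
    "SegregationObservation",
    "ModelFit",
    "expected_high_fraction",
    "segregation_ratio",
    "enumerate_f2_genotype_classes",
    "classify_phenotype",
    "pearson_gof",
    "chi2_sf",
    "rank_models",
    "default_candidate_models",
    "SegregationModelSelection",
    "SegregationResults",
]

WILD = "W"
CULTIVAR = "c"

#: genotype classes at one locus: homozygous wild, heterozygous, homozygous cultivar
GENOTYPE_CLASSES = ("WW", "Wc", "cc")
#: F2 marginal probabilities of the classes above (1:2:1 segregation)
GENOTYPE_CLASS_PROBS = (0.25, 0.5, 0.25)

ENUMERATION_LIMIT = 8


class Mode(str, Enum):
    """Inheritance requirement of one locus for the high phenotype."""

    RECESSIVE = "recessive"
    DOMINANT = "dominant"


@dataclass(frozen=True)
class LocusRequirement:
    """One locus of a gene model.

    Parameters
    ----------
    label : str
        Short identifier; lower case is conventionally recessive, upper case
        dominant, but only ``mode`` is authoritative.
    mode : Mode or str
        ``"recessive"`` (phenotype requires homozygous wild-parent alleles)
        or ``"dominant"`` (requires at least one wild-parent allele).
    """

    label: str
    mode: Mode

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        if not self.label:
            raise ValueError("locus label must be non-empty")

    @property
    def satisfied_probability(self) -> float:
        """F2 probability that this locus meets its requirement."""
        return 0.25 if self.mode is Mode.RECESSIVE else 0.75

    def satisfied_by(self, alleles: Sequence[str]) -> bool:
        """Whether an unordered allele pair meets the requirement."""
        n_wild = sum(1 for a in alleles if a == WILD)
        if self.mode is Mode.RECESSIVE:
            return n_wild == 2
        return n_wild >= 1


@dataclass(frozen=True)
class GeneticModel:
    """An ordered set of unlinked locus requirements defining "high"."""

    loci: tuple[LocusRequirement, ...]

    def __init__(self, loci: Iterable[LocusRequirement]):
        object.__setattr__(self, "loci", tuple(loci))
        if len(self.loci) < 1:
            raise ValueError("model must contain ≥1 locus")
        labels = [l.label for l in self.loci]
        if len(set(labels)) != len(labels):
            raise ValueError(f"locus labels must be unique, got {labels}")

    @classmethod
    def from_spec(cls, spec: str) -> "GeneticModel":
        """Build from a compact string like ``"a-b-C-D"``.

        Lower-case letters are recessive loci, upper-case dominant.
        """
        parts = [p for p in spec.replace(" ", "").split("-") if p]
        return cls(
            LocusRequirement(p, Mode.RECESSIVE if p.islower() else Mode.DOMINANT)
            for p in parts
        )

    @property
    def name(self) -> str:
        return " - ".join(l.label for l in self.loci)

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class SegregationObservation:
    """Observed F2 counts of the high and low phenotype classes."""

    n_high: int
    n_low: int

    def __post_init__(self) -> None:
        if self.n_high < 0 or self.n_low < 0:
            raise ValueError("counts must be non-negative")
        if self.n_high + self.n_low < 1:
            raise ValueError("total count must be ≥1")

    @property
    def n(self) -> int:
        return self.n_high + self.n_low

    @property
    def observed_ratio(self) -> str:
        """Observed low:high odds as ``"1:k"`` (e.g. 12:380 -> ``"1:32"``)."""
        if self.n_high == 0:
            raise ValueError("no high plants observed; ratio undefined")
        return f"1:{_round_half_away(self.n_low / self.n_high)}"


@dataclass(frozen=True)
class ModelFit:
    """Goodness-of-fit of one gene model against observed counts."""

    model: GeneticModel
    f_high: float
    ratio: str
    chi2: float
    df: int
    p: float
    basis: str


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def expected_high_fraction(model: GeneticModel) -> float:
    """Expected F2 fraction of high plants under independent assortment.

    The product over loci of 1/4 (recessive) or 3/4 (dominant): the
    probability that a selfed-F1 offspring satisfies every locus requirement.
    """
    f = 1.0
    for locus in model.loci:
        f *= locus.satisfied_probability
    return f


def segregation_ratio(model: GeneticModel) -> str:
    """Low:high odds as a display string ``"1:k"``.

    k is ``(1 - f) / f`` rounded to the nearest integer, half away from
    zero.  Exact odds may be non-integer (e.g. 61:3 prints as ``"1:20"``).
    """
    f = expected_high_fraction(model)
    return f"1:{_round_half_away((1.0 - f) / f)}"


def enumerate_f2_genotype_classes(model: GeneticModel) -> pd.DataFrame:
    """Joint F2 genotype-class table: brute-force oracle for the closed form.

    Returns one row per combination of per-locus classes in
    ``{WW, Wc, cc}`` with columns per locus label, ``probability`` (product
    of 1/4, 1/2, 1/4 marginals) and ``high`` (phenotype under ``model``).
    """
    if len(model) > ENUMERATION_LIMIT:
        raise ValueError(
            f"enumeration limit: {len(model)} loci exceeds {ENUMERATION_LIMIT}"
        )
    labels = [l.label for l in model.loci]
    rows = []
    for combo in itertools.product(
        range(len(GENOTYPE_CLASSES)), repeat=len(labels)
    ):
        classes = [GENOTYPE_CLASSES[i] for i in combo]
        prob = math.prod(GENOTYPE_CLASS_PROBS[i] for i in combo)
        genotype = {lab: tuple(cls) for lab, cls in zip(labels, classes)}
        rows.append(
            dict(zip(labels, classes))
            | {"probability": prob, "high": classify_phenotype(genotype, model)}
        )
    return pd.DataFrame(rows)


def classify_phenotype(
    genotype: Mapping[str, Sequence[str]], model: GeneticModel
) -> bool:
    """High/low call for one plant.

    ``genotype`` maps locus label to an unordered allele pair over
    ``{"W", "c"}`` (wild / cultivar); phase is irrelevant.  True iff every
    recessive locus is homozygous wild and every dominant locus carries at
    least one wild allele.
    """
    for locus in model.loci:
        if locus.label not in genotype:
            raise KeyError(f"genotype missing locus {locus.label!r}")
        if not locus.satisfied_by(genotype[locus.label]):
            return False
    return True


def chi2_sf(x: float) -> float:
    """Upper-tail probability of the chi-square distribution, df = 1."""
    if x < 0:
        raise ValueError("chi-square statistic must be ≥0")
    return float(stats.chi2.sf(x, df=1))


def pearson_gof(
    obs: SegregationObservation,
    f_high: float,
    *,
    continuity_correction: bool = False,
) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit of observed counts to a high fraction.

    Two cells (high, low), expected ``n*f`` and ``n*(1-f)``; df = 1, no
    parameters estimated.  No continuity correction by default; the Yates
    correction is available behind ``continuity_correction``.

    Returns ``(chi2, df, p)``.
    """
    if not 0.0 < f_high < 1.0:
        raise ValueError(f"expected fraction must be in (0,1), got {f_high}")
    n = obs.n
    exp_high = n * f_high
    exp_low = n * (1.0 - f_high)
    if continuity_correction:
        dev_h = abs(obs.n_high - exp_high) - 0.5
        dev_l = abs(obs.n_low - exp_low) - 0.5
        chi2 = max(dev_h, 0.0) ** 2 / exp_high + max(dev_l, 0.0) ** 2 / exp_low
    else:
        chi2 = (obs.n_high - exp_high) ** 2 / exp_high + (
            obs.n_low - exp_low
        ) ** 2 / exp_low
    return chi2, 1, chi2_sf(chi2)


def _basis_fraction(model: GeneticModel, basis: str) -> float:
    if basis == "exact":
        return expected_high_fraction(model)
    if basis == "printed_ratio":
        # reconstruct f from the rounded 1:k display ratio
        k = int(segregation_ratio(model).split(":")[1])
        return 1.0 / (k + 1)
    raise ValueError(f"basis must be 'exact' or 'printed_ratio', got {basis!r}")


def rank_models(
    obs: SegregationObservation,
    models: Sequence[GeneticModel],
    basis: str = "printed_ratio",
    *,
    continuity_correction: bool = False,
) -> list[ModelFit]:
    """Fit every candidate model and sort by goodness of fit.

    Sorted by descending p (equivalently ascending chi-square at fixed df);
    ties broken by fewer loci, then lexicographic model name.  ``basis``
    chooses the expected fraction: ``"exact"`` (product of 1/4 and 3/4
    factors) or ``"printed_ratio"`` (reconstructed from the rounded 1:k
    ratio as 1/(k+1), matching published segregation tables).
    """
    if len(models) < 1:
        raise ValueError("need ≥1 candidate model")
    fits = []
    for model in models:
        f = _basis_fraction(model, basis)
        chi2, df, p = pearson_gof(
            obs, f, continuity_correction=continuity_correction
        )
        fits.append(
            ModelFit(
                model=model,
                f_high=f,
                ratio=segregation_ratio(model),
                chi2=chi2,
                df=df,
                p=p,
                basis=basis,
            )
        )
    order = sorted(
        range(len(fits)),
        key=lambda i: (-fits[i].p, len(fits[i].model), fits[i].model.name, i),
    )
    return [fits[i] for i in order]


def default_candidate_models() -> list[GeneticModel]:
    """The six candidate gene models tested against the F2 segregation:
    two to four loci, recessive (lower case) or dominant (upper case)."""
    return [
        GeneticModel.from_spec(s)
        for s in ("a-b", "a-b-C", "a-b-c", "a-b-C-D", "a-b-c-D", "a-b-c-d")
    ]


class SegregationModelSelection:
    """Model-selection problem: observed F2 counts vs candidate gene models.

    statsmodels-style container: construct from data, call :meth:`fit` for a
    :class:`SegregationResults`.

    Parameters
    ----------
    n_high, n_low : int
        Observed counts of the high and low phenotype classes.
    models : sequence of GeneticModel, optional
        Candidate models; defaults to :func:`default_candidate_models`.

    Examples
    --------
    >>> res = SegregationModelSelection(12, 380).fit()
    >>> res.best.model.name
    'a - b - C - D'
    """

    def __init__(
        self,
        n_high: int,
        n_low: int,
        models: Sequence[GeneticModel] | None = None,
    ):
        self.observation = SegregationObservation(n_high, n_low)
        self.models = list(models) if models is not None else default_candidate_models()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        models: Sequence[GeneticModel] | None = None,
    ) -> "SegregationModelSelection":
        """Build from a one-row frame with ``n_high`` and ``n_low`` columns."""
        if len(data) != 1:
            raise ValueError("expected exactly one observation row")
        row = data.iloc[0]
        return cls(int(row["n_high"]), int(row["n_low"]), models)

    def fit(
        self, basis: str = "printed_ratio", *, continuity_correction: bool = False
    ) -> "SegregationResults":
        fits = rank_models(
            self.observation,
            self.models,
            basis,
            continuity_correction=continuity_correction,
        )
        return SegregationResults(self, fits, basis)


class SegregationResults:
    """Ranked goodness-of-fit results for a set of candidate gene models."""

    def __init__(
        self,
        model: SegregationModelSelection,
        fits: list[ModelFit],
        basis: str,
    ):
        self.model = model
        self.fits = fits
        self.basis = basis

    @property
    def best(self) -> ModelFit:
        """Highest-p (best-fitting) model."""
        return self.fits[0]

    def rejected(self, alpha: float = 0.05) -> list[ModelFit]:
        """Models rejected at significance level alpha."""
        return [f for f in self.fits if f.p < alpha]

    def to_frame(self) -> pd.DataFrame:
        """Full-precision results table, one row per model, rank order."""
        return pd.DataFrame(
            {
                "model": [f.model.name for f in self.fits],
                "ratio": [f.ratio for f in self.fits],
                "f_high": [f.f_high for f in self.fits],
                "basis": [f.basis for f in self.fits],
                "chi2": [f.chi2 for f in self.fits],
                "df": [f.df for f in self.fits],
                "p": [f.p for f in self.fits],
                "rank": np.arange(1, len(self.fits) + 1),
            }
        )

    def summary(self, *, threshold_p: bool = True) -> str:
        """Printable table: model, segregation ratio, chi2 (2 dp), p.

        With ``threshold_p`` p-values below 0.01 / 0.05 print as ``< 0.01``
        / ``< 0.05``; otherwise at 2 dp.
        """
        obs = self.model.observation
        lines = [
            "Segregation model selection (Pearson GOF, df=1, "
            f"basis={self.basis})",
            f"observed high:low = {obs.n_high}:{obs.n_low} "
            f"({obs.observed_ratio}), n = {obs.n}",
            "",
            f"{'model':<16}{'segregation':<13}{'chi2':>8}  {'p-value':<8}",
        ]
        for f in self.fits:
            if threshold_p and f.p < 0.01:
                p_str = "< 0.01"
            elif threshold_p and f.p < 0.05:
                p_str = "< 0.05"
            else:
                p_str = f"{f.p:.2f}"
            lines.append(
                f"{f.model.name:<16}{f.ratio:<13}{f.chi2:>8.2f}  {p_str:<8}"
            )
        return "\n".join(lines)
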