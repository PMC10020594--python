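"""Synthetic F2 populations with the statistical structure of the assay.

Emulates a selfed-F1 (F2) population of a cultivated × wild tomato cross in
which a "high terpene" phenotype segregates at 2–4 unlinked loci, each
recessive or dominant.  Generated per-plant measurements mirror the real
assay tables:

* class-conditional, right-skewed (lognormal) leaf 7-epizingiberene levels
  with a zero-inflated low class (the zero bin of the level histogram);
* trichome density per leaf disc (negative binomial), statistically
  independent of per-gland productivity;
* an independent active/lazy latent gland class with ~150-fold spread in
  per-gland terpene content, and storage-cavity volume proportional to
  gland content.

Every draw is deterministic given the config seed.  The writers emit the
CSV schemas consumed by the quantification and phenotype stages, so the
whole pipeline is testable end-to-end without any external data.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .genetics import (
    CULTIVAR,
    WILD,
    GeneticModel,
    Mode,
    SegregationObservation,
    rank_models,
)
from .quantification import classify_high_low, parental_reference

__all__ = [
    "SimulationConfig",
    "simulate_genotype",
    "simulate_population",
    "simulate_high_counts",
    "recovery_experiment",
    "write_measurement_tables",
]

#: picolitre of storage cavity per ng of gland terpene content
#: (anchored to the 25.0 pl / 12.3 ng-per-gland control pairing)
CAVITY_PL_PER_NG = 25.0 / 12.3

#: leaf area sampled per mg fresh weight, mm²/mg — couples per-mm² trichome
#: density and per-gland content to a leaf-level total (ng/mg FW)
LEAF_MM2_PER_MG = 1.26

DISC_AREA_MM2 = math.pi * 2.0**2


class SimulationConfig(BaseModel):
    """Study conditions for one synthetic F2 population.

    Defaults follow the measured anchor points of the real cross: parental
    leaf 7-epizingiberene 70 ng/mg FW, F1 1.1 ng/mg, active glands 17.7
    ng/gland with a ~150-fold active:lazy spread, four parental replicates.
    """

    model: str = "a-b-C-D"
    n_plants: int = Field(392, ge=1)
    seed: int = 0
    high_level_mean: float = Field(70.0, gt=0)
    high_cv: float = Field(0.3, ge=0)
    low_level_mean: float = Field(1.1, gt=0)
    low_cv: float = Field(0.8, ge=0)
    zero_fraction_low: float = Field(0.8, ge=0, le=1)
    density_mean: float = Field(50.0, gt=0)
    density_dispersion: float = Field(8.0, gt=0)
    active_gland_ng: float = Field(17.7, gt=0)
    lazy_gland_ng: float = Field(17.7 / 150.0, gt=0)
    gland_cv: float = Field(0.2, ge=0)
    active_fraction: float = Field(0.5, ge=0, le=1)
    #: correlation knob between the high-phenotype loci and gland activity;
    #: 0 = independent traits (the default conclusion of the cross)
    activity_phenotype_corr: float = Field(0.0, ge=0, le=1)
    parental_n: int = Field(4, ge=2)

    @field_validator("model")
    @classmethod
    def _parseable(cls, v: str) -> str:
        GeneticModel.from_spec(v)
        return v

    @model_validator(mode="after")
    def _active_exceeds_lazy(self) -> "SimulationConfig":
        if self.active_gland_ng <= self.lazy_gland_ng:
            raise ValueError("active_gland_ng must exceed lazy_gland_ng")
        return self

    @property
    def genetic_model(self) -> GeneticModel:
        return GeneticModel.from_spec(self.model)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and CV."""
    sigma2 = math.log(1.0 + cv**2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def simulate_genotype(
    model: GeneticModel, rng: np.random.Generator
) -> dict[str, tuple[str, str]]:
    """One F2 genotype: per locus two alleles drawn independently and
    uniformly from {wild, cultivar} (selfing of a fully heterozygous F1)."""
    alleles = (WILD, CULTIVAR)
    return {
        locus.label: (
            alleles[rng.integers(0, 2)],
            alleles[rng.integers(0, 2)],
        )
        for locus in model.loci
    }


def _simulate_wild_counts(
    model: GeneticModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, n_loci) array of wild-allele counts (0/1/2) per plant and locus."""
    return rng.binomial(2, 0.5, size=(n, len(model)))


def _satisfied(model: GeneticModel, wild_counts: np.ndarray) -> np.ndarray:
    ok = np.ones(wild_counts.shape[0], dtype=bool)
    for j, locus in enumerate(model.loci):
        if locus.mode is Mode.RECESSIVE:
            ok &= wild_counts[:, j] == 2
        else:
            ok &= wild_counts[:, j] >= 1
    return ok


def simulate_high_counts(
    model: GeneticModel, n: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """High-phenotype counts of ``reps`` simulated F2 populations of size
    ``n`` — genotype-level forward simulation, vectorised over populations."""
    wc = rng.binomial(2, 0.5, size=(reps * n, len(model)))
    high = _satisfied(model, wc).reshape(reps, n)
    return high.sum(axis=1)


def _genotype_strings(
    model: GeneticModel, wild_counts: np.ndarray
) -> list[str]:
    per_locus = []
    for j, locus in enumerate(model.loci):
        cls = np.array(["cc", "Wc", "WW"])[wild_counts[:, j]]
        per_locus.append(np.char.add(locus.label + ":", cls))
    combined = per_locus[0]
    for col in per_locus[1:]:
        combined = np.char.add(np.char.add(combined, ";"), col)
    return list(combined)


def simulate_population(cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate one F2 population; one row per plant.

    Columns: ``plant_id, genotype, phenotype_class, terpene_ng_per_mg,
    density_per_disc, per_mm2, latent_activity, gland_ng, cavity_pl,
    total_terpene_ng_per_mg``.  Deterministic given ``cfg.seed``.
    """
    model = cfg.genetic_model
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_plants

    wc = _simulate_wild_counts(model, n, rng)
    high = _satisfied(model, wc)

    # class-conditional leaf 7epiZ level, zero-inflated in the low class
    mu_h, sg_h = _lognormal_params(cfg.high_level_mean, max(cfg.high_cv, 1e-9))
    mu_l, sg_l = _lognormal_params(cfg.low_level_mean, max(cfg.low_cv, 1e-9))
    level = np.where(
        high,
        rng.lognormal(mu_h, sg_h, size=n),
        rng.lognormal(mu_l, sg_l, size=n),
    )
    zero = (~high) & (rng.random(n) < cfg.zero_fraction_low)
    level[zero] = 0.0

    # trichome density: overdispersed counts, independent of phenotype
    r = cfg.density_dispersion
    p = r / (r + cfg.density_mean)
    density = rng.negative_binomial(r, p, size=n)

    # active/lazy gland class, by default independent of the phenotype loci
    active = rng.random(n) < cfg.active_fraction
    if cfg.activity_phenotype_corr > 0:
        couple = rng.random(n) < cfg.activity_phenotype_corr
        active = np.where(couple, high, active)
    gland_mean = np.where(active, cfg.active_gland_ng, cfg.lazy_gland_ng)
    if cfg.gland_cv > 0:
        sg2 = math.log(1.0 + cfg.gland_cv**2)
        gland = gland_mean * rng.lognormal(
            -sg2 / 2.0, math.sqrt(sg2), size=n
        )
    else:
        gland = gland_mean.astype(float)

    cavity = gland * CAVITY_PL_PER_NG
    per_mm2 = density / DISC_AREA_MM2
    total = per_mm2 * LEAF_MM2_PER_MG * gland

    return pd.DataFrame(
        {
            "plant_id": [f"F2-{i + 1:04d}" for i in range(n)],
            "genotype": _genotype_strings(model, wc),
            "phenotype_class": np.where(high, "high", "low"),
            "terpene_ng_per_mg": level,
            "density_per_disc": density,
            "per_mm2": per_mm2,
            "latent_activity": np.where(active, "active", "lazy"),
            "gland_ng": gland,
            "cavity_pl": cavity,
            "total_terpene_ng_per_mg": total,
        }
    )


def parse_genotype(s: str) -> dict[str, tuple[str, str]]:
    """Inverse of the ``genotype`` column encoding (``"a:Wc;b:WW"``)."""
    out = {}
    for part in s.split(";"):
        label, cls = part.split(":")
        out[label] = (cls[0], cls[1])
    return out


def recovery_experiment(
    cfg: SimulationConfig,
    candidates: Sequence[GeneticModel],
    reps: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Can the pipeline recover the generating gene model?

    Per replicate: simulate a population, build a parental reference from
    ``cfg.parental_n`` draws of the high-level distribution, classify every
    plant high/low against it, then rank the candidate models by Pearson
    GOF (exact basis).  Returns one row per candidate with its rejection
    rate at ``alpha`` and how often it ranked first.
    """
    if reps < 1:
        raise ValueError("need ≥1 replicate")
    rng = np.random.default_rng(cfg.seed)
    mu_h, sg_h = _lognormal_params(cfg.high_level_mean, max(cfg.high_cv, 1e-9))
    true_name = cfg.genetic_model.name
    reject = {m.name: 0 for m in candidates}
    best = {m.name: 0 for m in candidates}
    for rep in range(reps):
        rep_cfg = cfg.model_copy(
            update={"seed": int(rng.integers(0, 2**31 - 1))}
        )
        pop = simulate_population(rep_cfg)
        ref = parental_reference(
            np.random.default_rng(rep_cfg.seed + 1).lognormal(
                mu_h, sg_h, size=cfg.parental_n
            )
        )
        calls = np.array(
            [classify_high_low(v, ref) for v in pop["terpene_ng_per_mg"]]
        )
        n_high = int((calls == "high").sum())
        obs = SegregationObservation(n_high, cfg.n_plants - n_high)
        fits = rank_models(obs, candidates, basis="exact")
        best[fits[0].model.name] += 1
        for f in fits:
            if f.p < alpha:
                reject[f.model.name] += 1
    return pd.DataFrame(
        {
            "model": [m.name for m in candidates],
            "is_true": [m.name == true_name for m in candidates],
            "rejection_rate": [reject[m.name] / reps for m in candidates],
            "best_model_frequency": [best[m.name] / reps for m in candidates],
        }
    )


# ---------------------------------------------------------------------------
# measurement-table writers (CSV schemas of the consuming stages)

LEAF_META = dict(
    basis="fresh_weight",
    fresh_weight_mg=50.0,
    extraction_volume_ul=1000.0,
    injection_volume_ul=2.0,
    dilution=1.0,
)
GLAND_META = dict(
    basis="glands",
    n_glands=150,
    extraction_volume_ul=300.0,
    injection_volume_ul=1.0,
    dilution=1.0,
)
IS_AREA = 1.0e5
#: calibration slope used when inverting the pipeline (ng per unit
#: normalised area); the emitted response-factor table carries the same value
RF_SLOPE = 1.0
#: fraction of the gland terpene total attributed to the plastidial proxy
#: compound vs the cytosolic one in the emitted peak tables
PLASTIDIAL_SHARE = 0.9


def _peak_area(target_ng_per_basis: float, meta: Mapping) -> float:
    denom = (
        meta["fresh_weight_mg"]
        if meta["basis"] == "fresh_weight"
        else meta["n_glands"]
    )
    vol = meta["extraction_volume_ul"] / meta["injection_volume_ul"]
    return target_ng_per_basis / RF_SLOPE / meta["dilution"] / vol * denom * IS_AREA


def write_measurement_tables(
    pop: pd.DataFrame, outdir: str | Path, cfg: SimulationConfig
) -> dict[str, Path]:
    """Emit the CSV tables the quantification/phenotype stages consume.

    Peak areas are constructed by inverting the normalisation pipeline, so
    running the quantification stage on these files recovers the simulated
    ng quantities.  Writes ``peaks.csv``, ``sample_meta.csv``,
    ``response_factors.csv``, ``trichome_counts.csv``, ``cavities.csv`` and
    ``ground_truth.csv``; returns their paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 7)

    peaks, metas, counts, cavities = [], [], [], []
    for row in pop.itertuples(index=False):
        leaf_id = f"{row.plant_id}_leaf"
        gland_id = f"{row.plant_id}_glands"
        lm = {"sample_id": leaf_id, **LEAF_META}
        gm = {"sample_id": gland_id, **GLAND_META}
        metas += [lm, gm]
        peaks.append(
            dict(
                sample_id=leaf_id,
                compound="7-epizingiberene",
                peak_area=_peak_area(row.terpene_ng_per_mg, lm),
                is_area=IS_AREA,
            )
        )
        for compound, share in (
            ("7-epizingiberene", PLASTIDIAL_SHARE),
            ("beta-caryophyllene", 1.0 - PLASTIDIAL_SHARE),
        ):
            peaks.append(
                dict(
                    sample_id=gland_id,
                    compound=compound,
                    peak_area=_peak_area(row.gland_ng * share, gm),
                    is_area=IS_AREA,
                )
            )
        # two discs per surface; per-disc counts split the two-sided total
        for side in ("abaxial", "adaxial"):
            for _ in range(2):
                counts.append(
                    dict(
                        plant_id=row.plant_id,
                        side=side,
                        disc_radius_mm=2.0,
                        trichome_type="typeVI",
                        count=int(rng.binomial(row.density_per_disc, 0.5)),
                    )
                )
        # three cavities per plant, height = 1.2 × width, volume matching
        # cavity_pl under the pi-free prolate-spheroid convention
        v_um3 = row.cavity_pl * 1000.0
        a = (v_um3 / 1.6) ** (1.0 / 3.0)
        for t in range(3):
            jitter = rng.normal(1.0, 0.03)
            cavities.append(
                dict(
                    plant_id=row.plant_id,
                    trichome_id=f"{row.plant_id}_t{t + 1}",
                    width_um=2.0 * a * jitter,
                    height_um=2.4 * a * jitter,
                )
            )

    paths = {
        "peaks": outdir / "peaks.csv",
        "sample_meta": outdir / "sample_meta.csv",
        "response_factors": outdir / "response_factors.csv",
        "trichome_counts": outdir / "trichome_counts.csv",
        "cavities": outdir / "cavities.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    pd.DataFrame(peaks).to_csv(paths["peaks"], index=False)
    meta_cols = [
        "sample_id",
        "basis",
        "fresh_weight_mg",
        "n_glands",
        "extraction_volume_ul",
        "injection_volume_ul",
        "dilution",
    ]
    pd.DataFrame(metas).reindex(columns=meta_cols).to_csv(
        paths["sample_meta"], index=False
    )
    pd.DataFrame(
        [
            dict(
                compound="7-epizingiberene",
                standard_compound="beta-caryophyllene",
                ng_per_unit_area=RF_SLOPE,
            ),
            dict(
                compound="beta-caryophyllene",
                standard_compound="beta-caryophyllene",
                ng_per_unit_area=RF_SLOPE,
            ),
        ]
    ).to_csv(paths["response_factors"], index=False)
    pd.DataFrame(counts).to_csv(paths["trichome_counts"], index=False)
    pd.DataFrame(cavities).to_csv(paths["cavities"], index=False)
    pop[
        ["plant_id", "genotype", "phenotype_class", "latent_activity"]
    ].to_csv(paths["ground_truth"], index=False)
    return paths
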