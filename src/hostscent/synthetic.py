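"""Synthetic fruit-volatilome and antennal-response generators.

The generators emulate the statistical structure of a multi-species fruit
headspace survey: 28 fruit species sampled with 3-8 replicates each (median 7),
several hundred volatile compounds shared by anywhere from one to almost all
species, low within-species variability relative to between-species
variability, and negative-control samples that carry a small set of
contaminant compounds.  Everything downstream (preprocessing, sharedness
indices, olfactory-ensemble screening, partial-correlation statistics) is
exercised on this output, so the defaults are fixed study conditions rather
than tuning knobs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHEMICAL_CLASSES",
    "CompoundMeta",
    "GeneratorConfig",
    "VolatilomeDataset",
    "generate_volatilome",
    "generate_intact_sliced",
    "generate_eag_table",
    "write_dataset",
    "read_dataset",
]

# Vocabulary of chemical classes assigned to generated compounds, with the
# sampling weights used by the generator (esters and terpenoids dominate fruit
# headspaces; a sizeable fraction of GC-MS features stays unidentified).
CHEMICAL_CLASSES: dict[str, float] = {
    "ester": 0.16,
    "terpenoid": 0.14,
    "alcohol": 0.08,
    "aldehyde": 0.07,
    "aromatic": 0.06,
    "GLV": 0.04,
    "hydrocarbon": 0.08,
    "ketone": 0.07,
    "ether": 0.03,
    "furanoid": 0.02,
    "amine": 0.02,
    "carboxylic_acid": 0.03,
    "organohalogen": 0.02,
    "organophosphorus": 0.01,
    "organosulfur": 0.02,
    "unknown": 0.15,
}

# Replicate counts per species are drawn on 3..8 with these weights, giving a
# median of 7 replicates and roughly 190 samples for 28 species.
_REPLICATE_SUPPORT = np.arange(3, 9)
_REPLICATE_WEIGHTS = np.array([0.05, 0.05, 0.10, 0.15, 0.40, 0.25])


@dataclass(frozen=True)
class CompoundMeta:
    """Per-compound metadata carried through the analysis as covariates."""

    compound_id: str
    chemical_class: str
    atmospheric_lifetime: float  # hours; persistence against OH oxidation
    depletion_rate: float  # arbitrary units; source-depletion speed

    def __post_init__(self) -> None:
        if self.chemical_class not in CHEMICAL_CLASSES:
            raise ValueError(f"unknown chemical class {self.chemical_class!r}")
        if not self.atmospheric_lifetime > 0:
            raise ValueError("atmospheric_lifetime must be > 0")
        if not self.depletion_rate > 0:
            raise ValueError("depletion_rate must be > 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic volatilome.

    ``sharedness_shape`` is the success parameter of the truncated geometric
    distribution of the number of emitting species per compound (support
    1..n_species-1, declining mass).  Abundances are log-normal: each compound
    has a base log-abundance, each emitting species a species-level offset
    (``between_species_sd``) and each sample a residual offset
    (``within_species_sd``); within an emitting species a compound is seen in
    a sample with probability ``within_species_detection_prob``.
    """

    n_species: int = 28
    replicates_range: tuple[int, int] = (3, 8)
    n_compounds: int = 600
    sharedness_shape: float = 0.12
    within_species_detection_prob: float = 0.8
    base_log_mean: float = 10.0
    base_log_sd: float = 1.5
    between_species_sd: float = 1.0
    within_species_sd: float = 0.45
    n_controls: int = 20
    contaminant_fraction: float = 0.05
    contaminant_detection_prob: float = 0.9
    contaminant_log_boost: float = 1.0
    condition: str = "intact"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        lo, hi = self.replicates_range
        if not (1 <= lo <= hi <= 50):
            raise ValueError("replicates_range must lie within [1, 50]")
        if not (0 < self.within_species_detection_prob <= 1):
            raise ValueError("within_species_detection_prob must be in (0, 1]")
        if not (0 < self.sharedness_shape < 1):
            raise ValueError("sharedness_shape must be in (0, 1)")
        if self.condition not in ("intact", "sliced"):
            raise ValueError("condition must be 'intact' or 'sliced'")


@dataclass
class VolatilomeDataset:
    """Samples x compounds abundance matrix with labels and controls."""

    samples: pd.DataFrame  # sample_id, species_id, condition, replicate
    abundance: pd.DataFrame  # index sample_id, columns compound_id, >= 0
    control: pd.DataFrame  # index control sample_id, columns compound_id
    compounds: list[CompoundMeta]
    meta: dict = field(default_factory=dict)

    def compound_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(c) for c in self.compounds])
        return df.set_index("compound_id")

    def validate(self) -> None:
        if (self.abundance.values < 0).any() or (self.control.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if list(self.abundance.index) != list(self.samples["sample_id"]):
            raise ValueError("abundance rows inconsistent with sample table")
        ids = [c.compound_id for c in self.compounds]
        if list(self.abundance.columns) != ids or list(self.control.columns) != ids:
            raise ValueError("matrix columns inconsistent with compound list")
        counts = self.samples.groupby("species_id").size()
        if counts.empty or (counts < 1).any():
            raise ValueError("every species needs at least one sample")


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    # Master seed spawns per-stage child streams by a fixed counter scheme.
    return np.random.default_rng([seed, stage])


def _truncated_geometric(rng: np.random.Generator, p: float, kmax: int,
                         size: int) -> np.ndarray:
    """Draw from P(k) ∝ (1-p)^(k-1) on support 1..kmax."""
    k = np.arange(1, kmax + 1)
    pmf = p * (1 - p) ** (k - 1)
    pmf /= pmf.sum()
    return rng.choice(k, size=size, p=pmf)


def _make_compounds(n: int, rng: np.random.Generator,
                    prefix: str = "cmp") -> list[CompoundMeta]:
    classes = rng.choice(list(CHEMICAL_CLASSES), size=n,
                         p=list(CHEMICAL_CLASSES.values()))
    # Atmospheric lifetimes span minutes to days (log-normal around ~1 day);
    # depletion rates are order-1 positive values.
    al = np.exp(rng.normal(np.log(24.0), 1.0, size=n))
    dep = np.exp(rng.normal(0.0, 0.5, size=n))
    width = len(str(n - 1))
    return [
        CompoundMeta(f"{prefix}{i:0{width}d}", classes[i], al[i], dep[i])
        for i in range(n)
    ]


def generate_volatilome(config: GeneratorConfig,
                        compounds: Sequence[CompoundMeta] | None = None,
                        ) -> VolatilomeDataset:
    """Generate one volatilome dataset under ``config``.

    ``compounds`` may carry pre-built metadata (used to share compound
    identities between the intact and sliced condition); otherwise metadata is
    drawn from the config seed.  Deterministic given the seed.
    """
    cfg = config
    rng_meta = _stage_rng(cfg.seed, 0)
    rng_design = _stage_rng(cfg.seed, 1)
    rng_noise = _stage_rng(cfg.seed, 2)
    rng_control = _stage_rng(cfg.seed, 3)

    if compounds is None:
        compounds = _make_compounds(cfg.n_compounds, rng_meta)
    elif len(compounds) != cfg.n_compounds:
        raise ValueError("compound metadata length does not match n_compounds")
    compound_ids = [c.compound_id for c in compounds]

    lo, hi = cfg.replicates_range
    support = np.arange(lo, hi + 1)
    if (lo, hi) == (3, 8):
        weights = _REPLICATE_WEIGHTS
    else:  # uniform over a non-default replicate interval
        weights = np.full(len(support), 1.0 / len(support))
    reps = rng_design.choice(support, size=cfg.n_species, p=weights)

    rows = []
    for s in range(cfg.n_species):
        sp = f"species{s:02d}"
        for r in range(reps[s]):
            rows.append((f"{sp}_{cfg.condition}_r{r}", sp, cfg.condition, r))
    samples = pd.DataFrame(rows, columns=["sample_id", "species_id",
                                          "condition", "replicate"])
    n_samples = len(samples)
    species_index = samples["species_id"].map(
        {f"species{s:02d}": s for s in range(cfg.n_species)}).to_numpy()

    # Design: which species emit each compound, and at what species-level mean.
    n_emit = _truncated_geometric(rng_design, cfg.sharedness_shape,
                                  cfg.n_species - 1, cfg.n_compounds)
    emitter = np.zeros((cfg.n_species, cfg.n_compounds), dtype=bool)
    for j in range(cfg.n_compounds):
        emitter[rng_design.choice(cfg.n_species, size=n_emit[j],
                                  replace=False), j] = True
    base = rng_design.normal(cfg.base_log_mean, cfg.base_log_sd,
                             size=cfg.n_compounds)
    species_mean = base[None, :] + rng_design.normal(
        0.0, cfg.between_species_sd, size=(cfg.n_species, cfg.n_compounds))

    emits = emitter[species_index, :]  # samples x compounds
    detected = emits & (rng_noise.random((n_samples, cfg.n_compounds))
                        < cfg.within_species_detection_prob)
    log_ab = (species_mean[species_index, :]
              + rng_noise.normal(0.0, cfg.within_species_sd,
                                 size=(n_samples, cfg.n_compounds)))
    abundance = np.where(detected, np.exp(log_ab), 0.0)

    # Controls: blank bags, except contaminant compounds present at elevated
    # levels so the control filter has something real to remove.
    n_contam = int(round(cfg.contaminant_fraction * cfg.n_compounds))
    contam = rng_control.choice(cfg.n_compounds, size=n_contam, replace=False)
    control = np.zeros((cfg.n_controls, cfg.n_compounds))
    if n_contam:
        seen = (rng_control.random((cfg.n_controls, n_contam))
                < cfg.contaminant_detection_prob)
        clog = (base[contam][None, :] + cfg.contaminant_log_boost
                + rng_control.normal(0.0, cfg.within_species_sd,
                                     size=(cfg.n_controls, n_contam)))
        control[:, contam] = np.where(seen, np.exp(clog), 0.0)

    ds = VolatilomeDataset(
        samples=samples,
        abundance=pd.DataFrame(abundance, index=samples["sample_id"].tolist(),
                               columns=compound_ids),
        control=pd.DataFrame(control,
                             index=[f"control_{cfg.condition}_r{i}"
                                    for i in range(cfg.n_controls)],
                             columns=compound_ids),
        compounds=list(compounds),
        meta={
            "config": asdict(cfg),
            "seed_scheme": {"metadata": [cfg.seed, 0], "design": [cfg.seed, 1],
                            "noise": [cfg.seed, 2], "control": [cfg.seed, 3]},
            "contaminants": [compound_ids[j] for j in sorted(contam)],
        },
    )
    ds.validate()
    return ds


def generate_intact_sliced(config: GeneratorConfig,
                           sliced_extra_factor: float = 665 / 511,
                           sliced_detection_boost: float = 0.1,
                           ) -> tuple[VolatilomeDataset, VolatilomeDataset]:
    """Generate a paired intact/sliced experiment.

    Sliced fruit emits a superset of the intact compounds: the sliced dataset
    carries extra wound-induced compounds and a higher within-species
    detection probability.  Compound metadata for the shared compounds is
    identical across the two datasets.
    """
    from dataclasses import replace

    n_sliced = int(round(config.n_compounds * sliced_extra_factor))
    rng_meta = _stage_rng(config.seed, 0)
    all_compounds = _make_compounds(n_sliced, rng_meta)
    intact = generate_volatilome(
        replace(config, condition="intact"),
        compounds=all_compounds[: config.n_compounds])
    sliced_cfg = replace(
        config,
        condition="sliced",
        n_compounds=n_sliced,
        seed=config.seed + 1,
        within_species_detection_prob=min(
            1.0, config.within_species_detection_prob + sliced_detection_boost),
    )
    sliced = generate_volatilome(sliced_cfg, compounds=all_compounds)
    return intact, sliced


def generate_eag_table(sharedness: pd.Series,
                       rho_target: float,
                       covariates: pd.DataFrame,
                       n_individuals: int = 20,
                       noise_sd: float = 0.3,
                       seed: int = 0,
                       individual_sd: float = 0.3,
                       baseline: float = np.log(10.0),
                       dose: float = -4.0) -> pd.DataFrame:
    """Build an antennal-response table with a known partial correlation.

    On the log-response scale, responses are a linear combination of the
    compound's sharedness (coefficient set so the partial Pearson correlation
    with sharedness — controlling for atmospheric lifetime, depletion rate and
    chemical class — equals ``rho_target``), linear covariate effects,
    per-individual offsets and Gaussian noise; the result is exponentiated
    onto a positive response scale so a log-equivalent Box-Cox normalization
    step is meaningful downstream.

    ``covariates`` is indexed by compound_id with columns
    ``atmospheric_lifetime``, ``depletion_rate``, ``chemical_class``.
    Returns a long table (individual_id, species_id, compound_id, dose,
    response).
    """
    if not abs(rho_target) < 1:
        raise ValueError("rho_target must lie strictly within (-1, 1)")
    s = sharedness.dropna()
    if len(s) < 3 or np.isclose(s.std(ddof=0), 0.0):
        raise ValueError("need >= 3 compounds with non-constant sharedness")
    cov = covariates.loc[s.index]
    rng = np.random.default_rng([seed, 10])

    # Residualize sharedness on the controlled covariates (compound level) so
    # the imposed coefficient translates exactly into a partial correlation.
    dummies = pd.get_dummies(cov["chemical_class"], drop_first=True,
                             dtype=float)
    design = np.column_stack([
        np.ones(len(s)),
        cov["atmospheric_lifetime"].to_numpy(float),
        cov["depletion_rate"].to_numpy(float),
        dummies.to_numpy(float) if dummies.shape[1] else
        np.empty((len(s), 0)),
    ])
    coef, *_ = np.linalg.lstsq(design, s.to_numpy(float), rcond=None)
    s_perp = s.to_numpy(float) - design @ coef
    sigma_s = s_perp.std(ddof=0)
    if np.isclose(sigma_s, 0.0):
        raise ValueError("sharedness is collinear with the covariates")
    beta = rho_target / np.sqrt(1 - rho_target**2) * noise_sd / sigma_s

    # Linear effects of the controlled covariates (standardized linearly so
    # they are removed exactly by the estimator's controls).
    al = cov["atmospheric_lifetime"].to_numpy(float)
    dep = cov["depletion_rate"].to_numpy(float)
    al_std = (al - al.mean()) / (al.std(ddof=0) or 1.0)
    dep_std = (dep - dep.mean()) / (dep.std(ddof=0) or 1.0)
    classes = cov["chemical_class"].astype("category")
    class_fx = rng.normal(0.0, 0.25, size=len(classes.cat.categories))
    compound_part = (beta * s_perp + 0.15 * al_std + 0.10 * dep_std
                     + class_fx[classes.cat.codes.to_numpy()])

    indiv_fx = rng.normal(0.0, individual_sd, size=n_individuals)
    rows = []
    for i in range(n_individuals):
        eps = rng.normal(0.0, noise_sd, size=len(s))
        logr = baseline + indiv_fx[i] + compound_part + eps
        rows.append(pd.DataFrame({
            "individual_id": f"ind{i:02d}",
            "species_id": "fly_sim",
            "compound_id": s.index,
            "dose": dose,
            "response": np.exp(logr),
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# CSV round-trip (long-format abundances plus a compound table and a JSON
# sidecar recording the config and seed scheme).

def write_dataset(ds: VolatilomeDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long = (ds.abundance.rename_axis("sample_id").reset_index()
            .melt(id_vars="sample_id", var_name="compound_id",
                  value_name="abundance"))
    long = long.merge(ds.samples, on="sample_id")
    long = long[long["abundance"] > 0]
    long[["sample_id", "species_id", "condition", "replicate",
          "compound_id", "abundance"]].to_csv(outdir / "samples.csv",
                                              index=False)
    ctrl = (ds.control.rename_axis("sample_id").reset_index()
            .melt(id_vars="sample_id", var_name="compound_id",
                  value_name="abundance"))
    ctrl[ctrl["abundance"] > 0].to_csv(outdir / "controls.csv", index=False)
    ds.compound_frame().to_csv(outdir / "compounds.csv")
    # the long CSV omits zero rows, so the sidecar keeps the sample roster
    sidecar = dict(ds.meta)
    sidecar["samples"] = ds.samples.to_dict(orient="records")
    (outdir / "generator.json").write_text(json.dumps(sidecar, indent=2))


def read_dataset(indir: str | Path) -> VolatilomeDataset:
    indir = Path(indir)
    meta = json.loads((indir / "generator.json").read_text())
    comp = pd.read_csv(indir / "compounds.csv")
    compounds = [CompoundMeta(r.compound_id, r.chemical_class,
                              r.atmospheric_lifetime, r.depletion_rate)
                 for r in comp.itertuples()]
    ids = [c.compound_id for c in compounds]
    long = pd.read_csv(indir / "samples.csv")
    samples = pd.DataFrame(meta.pop("samples"))
    abundance = (long.pivot(index="sample_id", columns="compound_id",
                            values="abundance")
                 .reindex(index=samples["sample_id"], columns=ids)
                 .fillna(0.0))
    ctrl_long = pd.read_csv(indir / "controls.csv")
    n_controls = meta["config"]["n_controls"]
    cond = meta["config"]["condition"]
    ctrl_index = [f"control_{cond}_r{i}" for i in range(n_controls)]
    control = (ctrl_long.pivot(index="sample_id", columns="compound_id",
                               values="abundance")
               .reindex(index=ctrl_index, columns=ids).fillna(0.0))
    ds = VolatilomeDataset(samples=samples, abundance=abundance,
                           control=control, compounds=compounds, meta=meta)
    ds.validate()
    return ds
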