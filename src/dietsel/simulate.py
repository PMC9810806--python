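"""Synthetic paired gut/water metabarcoding study with known selectivity.

The generator emulates a quarterly lake survey: at each site and season
an ambient eukaryote community is drawn from a season-specific Dirichlet
baseline, the consumer's gut composition is "ingestion proportional to
availability times preference" (q ∝ w·p), a dominant fraction of gut
reads belongs to the consumer itself, and reads are multinomial at
realistic depths (tens of thousands per water sample, a few hundred
non-consumer reads per gut sample). Environmental covariates follow
seasonal means with a shared trophic latent factor driving TN, TP and
Chl-a up and transparency down.

Ground truth (ambient proportions p, diet proportions q, electivity
E = (q-p)/(q+p)) is returned alongside the tables so every downstream
estimator can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ENV_VARS, RANKS, SEASONS, UNASSIGNED, OtuTable, SampleFrame, TaxonomyMap

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "simulate_study",
    "truth_electivity",
    "study_preset",
    "CONSUMER_OTU",
    "CONSUMER_GENUS",
]

CONSUMER_OTU = "OTU0000"
CONSUMER_GENUS = "Polyarthra"
CONSUMER_LINEAGE = (
    "Eukaryota",
    "Rotifera",
    "Eurotatoria",
    "Ploima",
    "Synchaetidae",
    "Polyarthra",
)

# Default community template: (class, phylum, n OTUs, baseline mass per
# season Dec/Mar/Jun/Sep). Seasonal succession: cryptophytes in winter,
# trebouxiophytes in spring, chlorophytes in summer, diatoms rising in
# autumn. Class-UNASSIGNED rows exercise the "unclassified X" buckets.
_COMMUNITY = (
    ("Chlorophyceae", "Chlorophyta", 8, (10.0, 14.0, 45.0, 25.0)),
    ("Cryptophyceae", "Cryptophyta", 4, (45.0, 12.0, 4.0, 8.0)),
    ("Trebouxiophyceae", "Chlorophyta", 4, (8.0, 30.0, 8.0, 8.0)),
    ("Bacillariophyceae", "Bacillariophyta", 4, (6.0, 8.0, 6.0, 18.0)),
    ("Dinophyceae", "Dinoflagellata", 4, (6.0, 8.0, 8.0, 10.0)),
    ("Chrysophyceae", "Chrysophyta", 3, (2.0, 3.0, 2.0, 4.0)),
    ("Synurophyceae", "Chrysophyta", 2, (1.5, 2.0, 1.5, 2.0)),
    ("Oligohymenophorea", "Ciliophora", 3, (5.0, 6.0, 6.0, 6.0)),
    ("Spirotrichea", "Ciliophora", 2, (4.0, 4.0, 4.0, 4.0)),
    ("Maxillopoda", "Arthropoda", 2, (6.0, 6.0, 8.0, 8.0)),
    ("Chytridiomycetes", "Chytridiomycota", 2, (2.0, 3.0, 2.0, 3.0)),
    (UNASSIGNED, "Chlorophyta", 1, (2.0, 2.0, 2.0, 2.0)),
    (UNASSIGNED, "Fungi", 1, (2.0, 2.0, 2.0, 2.0)),
)

# Season means for the 11 environmental variables (subtropical lake).
_ENV_MEANS: dict[str, tuple[float, float, float, float]] = {
    "Temp": (12.0, 18.0, 30.0, 27.0),
    "DO": (10.0, 9.0, 7.5, 8.0),
    "pH": (7.8, 8.0, 8.4, 8.2),
    "Salinity": (0.12, 0.12, 0.10, 0.11),
    "Dep": (4.0, 4.2, 4.5, 4.3),
    "SD": (0.8, 0.7, 0.5, 0.6),
    "Chl_a": (15.0, 20.0, 45.0, 35.0),
    "COD_Mn": (4.0, 4.5, 6.0, 5.5),
    "TP": (0.05, 0.06, 0.10, 0.08),
    "NH4_N": (0.30, 0.35, 0.50, 0.45),
    "TN": (1.2, 1.4, 2.0, 1.8),
}

# Loading of each variable on the trophic latent factor (+: eutrophic).
_ENV_LOADINGS: dict[str, float] = {"TN": 1.0, "TP": 1.0, "Chl_a": 1.0, "SD": -1.0}

# Seasonal mean of the latent trophic factor (eutrophic peak in summer).
_LATENT_SEASON_MEAN = {"Dec": -1.0, "Mar": -0.3, "Jun": 1.0, "Sep": 0.6}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study design."""

    n_sites: int = 3
    seasons: tuple[str, ...] = SEASONS
    n_taxa: int = 40
    dirichlet_concentration: float = 150.0
    selectivity_weights: Mapping[str, float] | None = None
    consumer_fraction: float = 0.9
    depth_water: int = 60_000
    depth_gut: int = 5_500
    env_latent_sd: float = 0.5
    env_latent_cv: float = 0.25
    env_noise_cv: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_taxa < 2:
            raise ValueError("need at least 1 site and 2 taxa")
        if not (0.0 <= self.consumer_fraction < 1.0):
            raise ValueError("consumer_fraction must lie in [0, 1): "
                             "no diet reads are possible at 1")
        if self.depth_water < 1 or self.depth_gut < 1:
            raise ValueError("sequencing depths must be >= 1")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.selectivity_weights is not None:
            if any(w <= 0 for w in self.selectivity_weights.values()):
                raise ValueError("selectivity weights must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "seasons" in raw:
            raw["seasons"] = tuple(raw["seasons"])
        return cls(**raw)


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth composition and electivity of the simulated study."""

    taxa: tuple[str, ...]
    weights: pd.Series  # taxon -> preference weight w
    site_p: pd.DataFrame  # (site, season) x taxon ambient proportions
    season_p: pd.DataFrame  # season x taxon, sites averaged
    season_q: pd.DataFrame  # season x taxon diet proportions (q ∝ w·p)
    latent: pd.Series  # (site, season) -> trophic latent factor

    def electivity(self, taxon: str, season: str) -> float:
        if taxon not in self.season_p.columns:
            raise KeyError(f"unknown taxon {taxon!r}")
        p = float(self.season_p.at[season, taxon])
        q = float(self.season_q.at[season, taxon])
        if p + q == 0.0:
            return 0.0
        return (q - p) / (q + p)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for season in self.season_p.index:
            for taxon in self.taxa:
                rows.append(
                    {
                        "taxon": taxon,
                        "season": season,
                        "p": self.season_p.at[season, taxon],
                        "q": self.season_q.at[season, taxon],
                        "E_true": self.electivity(taxon, season),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def truth_electivity(truth: SimTruth, taxon: str, season: str) -> float:
    """Exact electivity E = (q-p)/(q+p) from true proportions."""
    return truth.electivity(taxon, season)


@dataclass(frozen=True)
class SimStudy:
    gut: OtuTable
    water: OtuTable
    taxonomy: TaxonomyMap
    samples: SampleFrame
    truth: SimTruth
    config: SimConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gut": outdir / "gut_counts.tsv",
            "water": outdir / "water_counts.tsv",
            "taxonomy": outdir / "taxonomy.tsv",
            "samples": outdir / "samples.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.gut.to_tsv(paths["gut"])
        self.water.to_tsv(paths["water"])
        self.taxonomy.to_tsv(paths["taxonomy"])
        self.samples.to_tsv(paths["samples"])
        self.truth.to_tsv(paths["truth"])
        return paths


def _default_taxa(n_taxa: int):
    """Distribute n_taxa OTUs over the community template.

    Returns otu ids, lineages, and the season baseline matrix
    (seasons in SEASONS order x taxa), columns scaled so the community
    keeps the template's class-level seasonal structure.
    """
    counts = np.array([c[2] for c in _COMMUNITY], dtype=float)
    alloc = np.maximum(1, np.round(counts / counts.sum() * n_taxa).astype(int))
    # adjust to hit n_taxa exactly, nibbling from the largest classes
    while alloc.sum() > n_taxa:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_taxa:
        alloc[np.argmin(alloc)] += 1
    otu_ids: list[str] = []
    lineages: dict[str, tuple[str, ...]] = {}
    cols: list[np.ndarray] = []
    k = 0
    for (cls, phylum, _, season_mass), n in zip(_COMMUNITY, alloc):
        # uneven split within a class (geometric), a realistic rank-abundance
        split = 0.7 ** np.arange(n)
        split /= split.sum()
        for j in range(n):
            k += 1
            otu = f"OTU{k:04d}"
            otu_ids.append(otu)
            lineages[otu] = TaxonomyMap.canonicalise(
                [
                    "Eukaryota",
                    phylum,
                    cls,
                    UNASSIGNED,
                    UNASSIGNED,
                    f"{cls}_g{j + 1}" if cls != UNASSIGNED else UNASSIGNED,
                ]
            )
            cols.append(np.asarray(season_mass) * split[j])
    baseline = np.column_stack(cols)  # 4 x n_taxa
    baseline /= baseline.sum(axis=1, keepdims=True)
    return otu_ids, lineages, baseline


def _weights_vector(
    config: SimConfig, otu_ids: Sequence[str], lineages: Mapping[str, tuple[str, ...]]
) -> np.ndarray:
    w = np.ones(len(otu_ids))
    if config.selectivity_weights:
        class_idx = RANKS.index("class")
        for i, otu in enumerate(otu_ids):
            cls = lineages[otu][class_idx]
            if otu in config.selectivity_weights:
                w[i] = config.selectivity_weights[otu]
            elif cls in config.selectivity_weights:
                w[i] = config.selectivity_weights[cls]
    return w


def simulate_study(config: SimConfig | None = None) -> SimStudy:
    """Generate the paired gut/water study with ground truth.

    Deterministic for a fixed config (including seed).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    otu_ids, lineages, baseline = _default_taxa(config.n_taxa)
    season_index = {s: i for i, s in enumerate(SEASONS)}
    w = _weights_vector(config, otu_ids, lineages)

    gut_rows: dict[str, np.ndarray] = {}
    water_rows: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    site_p: dict[tuple[str, str], np.ndarray] = {}
    latent: dict[tuple[str, str], float] = {}

    for season in config.seasons:
        alpha = config.dirichlet_concentration * baseline[season_index[season]]
        for s in range(config.n_sites):
            site = f"S{s + 1}"
            p = rng.dirichlet(alpha)
            site_p[(site, season)] = p
            q = w * p
            q /= q.sum()

            water_id = f"A{s + 1}_{season}"
            water_rows[water_id] = rng.multinomial(config.depth_water, p)
            gut_id = f"P{s + 1}_{season}"
            n_consumer = rng.binomial(config.depth_gut, config.consumer_fraction)
            diet = rng.multinomial(config.depth_gut - n_consumer, q)
            gut_rows[gut_id] = np.concatenate([[n_consumer], diet])

            L = _LATENT_SEASON_MEAN.get(season, 0.0) + rng.normal(0.0, config.env_latent_sd)
            latent[(site, season)] = L
            env = {}
            for var in ENV_VARS:
                mean = _ENV_MEANS[var][season_index[season]]
                load = _ENV_LOADINGS.get(var, 0.0)
                scale = config.env_latent_cv * np.mean(_ENV_MEANS[var])
                noise = rng.normal(0.0, config.env_noise_cv * mean)
                env[var] = max(1e-3, mean + load * scale * L + noise)
            meta_rows[water_id] = {"site": site, "season": season, "compartment": "water", **env}
            meta_rows[gut_id] = {
                "site": site,
                "season": season,
                "compartment": "gut",
                **{v: np.nan for v in ENV_VARS},
            }

    water = OtuTable(
        pd.DataFrame.from_dict(water_rows, orient="index", columns=otu_ids).astype(np.int64)
    )
    gut = OtuTable(
        pd.DataFrame.from_dict(
            gut_rows, orient="index", columns=[CONSUMER_OTU] + otu_ids
        ).astype(np.int64)
    )
    taxonomy = TaxonomyMap({CONSUMER_OTU: CONSUMER_LINEAGE, **lineages})
    samples = SampleFrame(pd.DataFrame.from_dict(meta_rows, orient="index"))

    site_p_df = pd.DataFrame.from_dict(site_p, orient="index", columns=otu_ids)
    site_p_df.index = pd.MultiIndex.from_tuples(site_p_df.index, names=["site", "season"])
    season_p = site_p_df.groupby(level="season", sort=False).mean()
    season_p = season_p.loc[list(config.seasons)]
    season_q = season_p * w
    season_q = season_q.div(season_q.sum(axis=1), axis=0)
    truth = SimTruth(
        taxa=tuple(otu_ids),
        weights=pd.Series(w, index=otu_ids),
        site_p=site_p_df,
        season_p=season_p,
        season_q=season_q,
        latent=pd.Series(latent),
    )
    return SimStudy(gut=gut, water=water, taxonomy=taxonomy, samples=samples,
                    truth=truth, config=config)


def study_preset(seed: int = 0, **overrides) -> SimConfig:
    """Config emulating the observed feeding pattern: chrysophytes and
    synurophytes preferred (w=4), ciliates mildly preferred (w=1.5)."""
    weights = {
        "Chrysophyceae": 4.0,
        "Synurophyceae": 4.0,
        "Oligohymenophorea": 1.5,
        "Spirotrichea": 1.5,
    }
    return replace(SimConfig(seed=seed, selectivity_weights=weights), **overrides)
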