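"""End-to-end workflow: preprocess -> selectivity -> community -> ordination.

One call chains every stage of the gut-content vs ambient-water
analysis, writes tidy TSV outputs plus a machine-readable JSON report,
and records every threshold and seed used. Ordination constraints for
gut samples come from the environmental measurements of the paired
water sample at the same site and season.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import anosim, bray_curtis, cluster_order
from .io import (
    OtuTable,
    SampleFrame,
    TaxonomyMap,
    read_otu_table,
    read_sample_frame,
    read_taxonomy,
)
from .ordination import choose_method, cca, dca_gradient_length, forward_select, rda
from .preprocess import (
    aggregate_by_rank,
    rarefaction_curve,
    relative_abundance,
    remove_consumer_reads,
    shared_unique,
)
from .selectivity import (
    differential_enrichment,
    dominance_index,
    electivity_frame,
    electivity_table,
    enrichment_frame,
)
from .simulate import SimConfig, simulate_study

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, thresholds included."""

    outdir: Path
    simulate: SimConfig | None = None
    gut_path: Path | None = None
    water_path: Path | None = None
    taxonomy_path: Path | None = None
    samples_path: Path | None = None
    consumer: str = "Polyarthra"
    consumer_rank: str = "genus"
    rank: str = "class"
    e_threshold: float = 0.25
    fdr_alpha: float = 0.05
    selection_alpha: float = 0.05
    n_perm: int = 999
    rarefaction_points: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not (0 < self.e_threshold < 1 and 0 < self.fdr_alpha < 1
                and 0 < self.selection_alpha < 1):
            raise ValueError("thresholds out of range")
        if self.simulate is None and None in (
            self.gut_path, self.water_path, self.taxonomy_path, self.samples_path
        ):
            raise ValueError("provide either a simulate block or all four input paths")


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        study = simulate_study(config.simulate)
        return study.gut, study.water, study.taxonomy, study.samples
    return (
        read_otu_table(config.gut_path),
        read_otu_table(config.water_path),
        read_taxonomy(config.taxonomy_path),
        read_sample_frame(config.samples_path),
    )


def _combined_counts(gut: OtuTable, water: OtuTable) -> OtuTable:
    combined = pd.concat([gut.data, water.data]).fillna(0).astype(np.int64)
    return OtuTable(combined)


def _paired_env(meta: SampleFrame, gut_ids: list[str]) -> pd.DataFrame:
    """Env rows for gut samples, taken from the same-site same-season
    water sample."""
    df = meta.data
    water = df[df["compartment"] == "water"]
    env_cols = meta.env_columns
    rows = {}
    for sid in gut_ids:
        site, season = df.at[sid, "site"], df.at[sid, "season"]
        match = water[(water["site"] == site) & (water["season"] == season)]
        if len(match) != 1:
            raise ValueError(f"no unique paired water sample for gut sample {sid!r}")
        rows[sid] = match.iloc[0][env_cols].astype(float)
    return pd.DataFrame.from_dict(rows, orient="index")[env_cols]


def _ordinate(rel_df: pd.DataFrame, env: pd.DataFrame, config: RunConfig, label: str,
              report: dict, outdir: Path) -> None:
    gl = dca_gradient_length(rel_df)
    method = choose_method(gl.length)
    logger.info("%s: DCA axis-1 gradient length %.2f SD -> %s", label, gl.length, method)
    fit = rda(rel_df, env) if method == "RDA" else cca(rel_df, env)
    sel = forward_select(
        rel_df, env, method=method, alpha=config.selection_alpha,
        n_perm=config.n_perm, seed=config.seed,
    )
    fit.site_scores.to_csv(outdir / f"ordination_{label}_site_scores.tsv", sep="\t")
    fit.species_scores.to_csv(outdir / f"ordination_{label}_species_scores.tsv", sep="\t")
    fit.biplot_scores.to_csv(outdir / f"ordination_{label}_biplot_scores.tsv", sep="\t")
    sel.trace().to_csv(outdir / f"ordination_{label}_selection.tsv", sep="\t", index=False)
    report[f"ordination_{label}"] = {
        "gradient_length": gl.length,
        "method": method,
        "eigenvalues": [float(e) for e in fit.eigenvalues],
        "total_inertia": fit.total_inertia,
        "constrained_inertia": fit.constrained_inertia,
        "constrained_fraction": fit.constrained_fraction,
        "cum_explained_2axes": fit.cum_explained_2axes,
        "selected_variables": list(sel.selected),
        "selection_stopping_reason": sel.stopping_reason,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the report dict (also written as JSON).

    On a stage failure the exception propagates after the MANIFEST of
    completed stages is written, so partial outputs stay interpretable.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    report: dict = {
        "dietsel_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "thresholds": {
            "electivity": config.e_threshold,
            "fdr": config.fdr_alpha,
            "selection_alpha": config.selection_alpha,
            "n_permutations": config.n_perm,
        },
        "rank": config.rank,
        "consumer": {"name": config.consumer, "rank": config.consumer_rank},
    }
    manifest = outdir / "MANIFEST"

    def done(stage: str) -> None:
        completed.append(stage)
        manifest.write_text("\n".join(completed) + "\n")

    try:
        gut_raw, water, tax, meta = _load_inputs(config)
        if config.simulate is not None:
            for name, tbl in (("gut_counts", gut_raw), ("water_counts", water)):
                tbl.to_tsv(outdir / f"{name}.tsv")
            tax.to_tsv(outdir / "taxonomy.tsv")
            meta.to_tsv(outdir / "samples.tsv")
        done("load")

        removal = remove_consumer_reads(gut_raw, tax, config.consumer, config.consumer_rank)
        gut = removal.table
        removal.removed_reads.rename("removed_reads").to_csv(
            outdir / "consumer_removed_reads.tsv", sep="\t"
        )
        report["consumer_removal"] = {
            "reads_removed": int(removal.removed_reads.sum()),
            "empty_gut_samples": sorted(removal.empty_samples),
        }
        gut_class = aggregate_by_rank(gut, tax, config.rank)
        water_class = aggregate_by_rank(water, tax, config.rank)
        gut_rel = relative_abundance(gut_class)
        water_rel = relative_abundance(water_class)
        done("preprocess")

        curves = []
        for table in (gut, water):
            for sid in table.sample_ids:
                if table.data.loc[sid].sum() > 0:
                    curves.append(
                        rarefaction_curve(table, sid, n_points=config.rarefaction_points
                                          ).as_frame()
                    )
        pd.concat(curves).to_csv(outdir / "rarefaction.tsv", sep="\t", index=False)
        venn = shared_unique(gut, water)
        pd.DataFrame(
            {
                "set": ["shared", "unique_gut", "unique_water"],
                "n_otus": [len(venn.shared), len(venn.unique_a), len(venn.unique_b)],
                "otus": [
                    ",".join(sorted(venn.shared)),
                    ",".join(sorted(venn.unique_a)),
                    ",".join(sorted(venn.unique_b)),
                ],
            }
        ).to_csv(outdir / "venn.tsv", sep="\t", index=False)
        report["venn"] = {
            "shared": len(venn.shared),
            "unique_gut": len(venn.unique_a),
            "unique_water": len(venn.unique_b),
        }
        report["otu_counts"] = {
            "gut": int((gut.data.sum(axis=0) > 0).sum()),
            "water": int((water.data.sum(axis=0) > 0).sum()),
        }
        done("rarefaction_venn")

        dom = dominance_index(water_rel)
        records = electivity_table(
            gut_class, water_class, meta, rank=config.rank,
            threshold=config.e_threshold,
        )
        tidy = electivity_frame(records)
        tidy.to_csv(outdir / "electivity_tidy.tsv", sep="\t", index=False)
        wide_E = tidy.pivot(index="taxon", columns="group", values="E")
        wide_C = tidy.pivot(index="taxon", columns="group", values="classification")
        summary_tbl = pd.DataFrame({"Y": {d.taxon: d.Y for d in dom}})
        seasons = [s for s in ("Dec", "Mar", "Jun", "Sep") if s in wide_E.columns]
        for s in seasons:
            summary_tbl[f"E_{s}"] = wide_E[s]
            summary_tbl[f"selection_{s}"] = wide_C[s]
        summary_tbl = summary_tbl.sort_values("Y", ascending=False)
        summary_tbl.index.name = "taxon"
        summary_tbl.to_csv(outdir / "electivity_table.tsv", sep="\t", float_format="%.3f")
        enrich = differential_enrichment(gut_rel, water_rel, alpha=config.fdr_alpha)
        enrichment_frame(enrich).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report["selectivity"] = {
            "n_preference": int((tidy["classification"] == "preference").sum()),
            "n_discrimination": int((tidy["classification"] == "discrimination").sum()),
            "n_enriched_fdr": int(sum(r.significant for r in enrich)),
        }
        done("selectivity")

        combined = _combined_counts(gut_class, water_class)
        rel_combined = relative_abundance(combined).nonempty()
        dm = bray_curtis(rel_combined)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            outdir / "distance.tsv", sep="\t"
        )
        groups = {sid: str(meta.data.at[sid, "compartment"]) for sid in dm.ids}
        ar = anosim(dm, groups, n_perm=config.n_perm, seed=config.seed)
        order, _ = cluster_order(dm)
        (outdir / "cluster_order.txt").write_text("\n".join(order) + "\n")
        report["anosim"] = {
            "R": ar.R, "p": ar.p, "band": ar.band, "n_permutations": ar.n_permutations,
        }
        done("community")

        env_cols = meta.env_columns
        if env_cols:
            water_ids = [s for s in water_rel.nonempty().sample_ids]
            env_water = meta.env_matrix(water_ids)
            _ordinate(water_rel.nonempty().data.loc[water_ids], env_water,
                      config, "water", report, outdir)
            gut_ids = [s for s in gut_rel.nonempty().sample_ids]
            env_gut = _paired_env(meta, gut_ids)
            _ordinate(gut_rel.nonempty().data.loc[gut_ids], env_gut,
                      config, "gut", report, outdir)
            done("ordination")
        else:
            logger.warning("no environmental variables; skipping ordination")

        report["completed_stages"] = completed
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        done("report")
        return report
    finally:
        if completed:
            manifest.write_text("\n".join(completed) + "\n")
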