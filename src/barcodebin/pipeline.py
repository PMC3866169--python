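"""End-to-end orchestration: load -> filter -> distances -> cluster ->
concordance -> gap -> geography, with provenance and a summary report.

A run consumes either a FASTA + metadata pair or a synthetic fixture seed,
executes every stage with the configured parameters, and writes all stage
tables plus a ``summary.json`` into the output directory. Runs are
deterministic: the same configuration and inputs produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .cluster import cluster_dataset, neighbor_joining, write_assignment_tsv
from .concordance import (
    build_species_otu_map,
    classify_species,
    detect_barcode_sharing,
    diagnosability_summary,
    regional_report_table,
    round_half_up,
)
from .distance import build_distance_matrix, write_matrix_tsv
from .gap import accumulation_curve, intra_cluster_summary, species_gap_table, taxon_summary
from .geo import sharing_pair_geography, split_pair_table
from .records import BarcodeDataset
from .simulate import survey_fixture

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be set: ``fasta``+``metadata`` paths, or
    ``fixture_seed`` for the built-in synthetic fixture. ``regions`` limits
    the regional re-identification table; empty means every region present.
    """

    out_dir: str = "run"
    fasta: str | None = None
    metadata: str | None = None
    fixture_seed: int | None = None
    seed_threshold: float = 0.022
    refine_threshold: float = 0.04
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    max_iter: int = 100
    tol: float = 1e-6
    regions: list[str] = field(default_factory=list)
    accumulation_iterations: int = 100
    seed: int = 0

    def validate(self) -> None:
        from_files = self.fasta is not None and self.metadata is not None
        if from_files == (self.fixture_seed is not None):
            raise ValueError("set exactly one input: fasta+metadata or fixture_seed")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _pct(x: float) -> float:
    """Distance fraction as a percentage with two decimals; nan passes."""
    return math.nan if math.isnan(x) else round(100.0 * x, 2)


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Emits: dataset FASTA/metadata (for synthetic inputs), ``manifest.json``,
    ``distances.tsv``, ``clusters.tsv``, ``tree.nwk`` (when all distances
    are defined), ``concordance.tsv``, ``sharing.tsv``, ``sharing_geo.tsv``,
    ``gap_table.tsv``, ``taxon_summary.tsv``, ``intra_cluster.tsv``,
    ``split_pairs.tsv``, ``regional.tsv``, ``accumulation.tsv`` and
    ``summary.json``. A stage failure aborts with the stage name; outputs of
    completed stages are retained.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"config": asdict(cfg)}

    stage = "load"
    try:
        if cfg.fixture_seed is not None:
            ds, _truth = survey_fixture(cfg.fixture_seed)
            bio.write_dataset(ds, out / "dataset.fasta", out / "dataset.tsv")
            provenance["input"] = {"fixture_seed": cfg.fixture_seed}
        else:
            ds = bio.read_dataset(cfg.fasta, cfg.metadata)
            provenance["input"] = {
                "fasta": str(cfg.fasta),
                "fasta_sha256": _sha256(cfg.fasta),
                "metadata": str(cfg.metadata),
                "metadata_sha256": _sha256(cfg.metadata),
            }
        n_loaded = len(ds)
        ds = bio.filter_barcode_compliant(ds)
        manifest = bio.dataset_manifest(ds)
        manifest["n_loaded"] = n_loaded
        manifest["n_dropped_length_filter"] = n_loaded - len(ds)
        _write_json(manifest, out / "manifest.json")

        stage = "distances"
        dm = build_distance_matrix(ds)
        write_matrix_tsv(dm, out / "distances.tsv")

        stage = "clustering"
        ca = cluster_dataset(
            dm,
            seed_threshold=cfg.seed_threshold,
            refine_threshold=cfg.refine_threshold,
            mcl_inflation=cfg.mcl_inflation,
            mcl_expansion=cfg.mcl_expansion,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
        )
        write_assignment_tsv(ca, out / "clusters.tsv")
        tree_written = False
        if len(dm) >= 3 and not dm.undefined_pairs and not dm.invalid_pairs:
            (out / "tree.nwk").write_text(neighbor_joining(dm) + "\n")
            tree_written = True
        else:
            logger.warning("NJ tree skipped: undefined distances or too few taxa")

        stage = "concordance"
        smap = build_species_otu_map(ds, ca)
        report = classify_species(smap)
        pd.DataFrame(
            sorted(
                ({"species": sp, "category": cat.value} for sp, cat in report.category_of.items()),
                key=lambda r: r["species"],
            )
        ).to_csv(out / "concordance.tsv", sep="\t", index=False)
        sharing = detect_barcode_sharing(dm, ds, smap)
        sharing.to_csv(out / "sharing.tsv", sep="\t", index=False)

        stage = "geography"
        sharing_geo = sharing_pair_geography(ds, sharing)
        sharing_geo.to_csv(out / "sharing_geo.tsv", sep="\t", index=False)
        splits = split_pair_table(ds, ca, smap, dm)
        splits.to_csv(out / "split_pairs.tsv", sep="\t", index=False)
        sympatric_pairs = {
            frozenset((r.species_a, r.species_b))
            for r in sharing_geo.itertuples(index=False)
            if r.sympatric
        }
        diag = diagnosability_summary(sharing, report.n_species, sympatric_pairs)

        stage = "gap"
        gap_rows = species_gap_table(dm, ds)
        gap_rows.to_csv(out / "gap_table.tsv", sep="\t", index=False)
        tx_all = taxon_summary(gap_rows, dm, ds, grouping="all")
        tx_genus = taxon_summary(gap_rows, dm, ds, grouping="genus")
        pd.concat([tx_all, tx_genus], ignore_index=True).to_csv(
            out / "taxon_summary.tsv", sep="\t", index=False
        )
        cvar = intra_cluster_summary(dm, ca)
        cvar.per_cluster.to_csv(out / "intra_cluster.tsv", sep="\t", index=False)
        curve_sp = accumulation_curve(
            ds, "species", iterations=cfg.accumulation_iterations, seed=cfg.seed
        )
        curve_cl = accumulation_curve(
            ds, "cluster", iterations=cfg.accumulation_iterations, seed=cfg.seed, ca=ca
        )
        pd.DataFrame(
            {
                "n_specimens": curve_sp.x,
                "mean_species_richness": np.round(curve_sp.mean_richness, 4),
                "mean_cluster_richness": np.round(curve_cl.mean_richness, 4),
            }
        ).to_csv(out / "accumulation.tsv", sep="\t", index=False)

        stage = "regional"
        unknown = set(cfg.regions) - set(ds.regions)
        if unknown:
            raise ValueError(f"unknown region(s) in config: {sorted(unknown)}")
        regions = cfg.regions or ds.regions
        regional = regional_report_table(ds, sorted(regions), ca, dm)
        regional.to_csv(out / "regional.tsv", sep="\t", index=False)

        stage = "summary"
        row_all = tx_all.iloc[0]
        n_split_combos = len(splits)
        n_allopatric = int((splits["sympatric"] == False).sum()) if n_split_combos else 0  # noqa: E712
        summary = {
            "n_specimens": len(ds),
            "n_species": report.n_species,
            "n_clusters": report.n_clusters,
            "n_match": report.n_match,
            "n_share": report.n_share,
            "n_split": report.n_split,
            "n_mixture": report.counts["MIXTURE"],
            "match_pct": report.match_pct,
            "share_pct": report.share_pct,
            "split_pct": report.split_pct,
            "cluster_species_discrepancy_pct": round_half_up(
                100.0 * (report.n_clusters - report.n_species) / report.n_clusters
            ),
            "n_sharing_pairs": len(sharing),
            "n_identical_pairs": diag["n_identical_pairs"],
            "n_identical_sympatric_pairs": diag["n_identical_sympatric_pairs"],
            "diagnostic_pct": diag["diagnostic_pct"],
            "range_discriminated_pct": diag["range_discriminated_pct"],
            "n_split_combos": n_split_combos,
            "allopatric_split_pct": round_half_up(100.0 * n_allopatric / n_split_combos)
            if n_split_combos
            else math.nan,
            "mean_intra_pct": _pct(float(row_all["mean_intra"])),
            "mean_max_intra_pct": _pct(float(row_all["mean_max_intra"])),
            "mean_congeneric_pct": _pct(float(row_all["mean_congeneric"])),
            "mean_nn_pct": _pct(float(row_all["mean_nn"])),
            "n_multi_member_clusters": cvar.n_multi_clusters,
            "mean_intra_cluster_pct": _pct(cvar.grand_mean_intra),
            "mean_max_intra_cluster_pct": _pct(cvar.grand_mean_max),
            "n_saturated_pairs": len(dm.undefined_pairs),
            "n_invalid_pairs": len(dm.invalid_pairs),
            "tree_written": tree_written,
        }
        _write_json(summary, out / "summary.json")
        _write_json(provenance, out / "provenance.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
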