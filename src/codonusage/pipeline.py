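"""End-to-end orchestration of the codon-usage analysis.

Three entry points mirror the separable stages of the study design:

* :func:`run_simulate` — write a synthetic species panel as FASTA.
* :func:`run_filter` — apply the CDS quality filter per species.
* :func:`run_profile` — compute every per-species table (composition,
  RSCU, ENc + deviation histogram, neutrality fit, codon pairs, junction
  table, GC3 gradient) and, with two or more species, the cross-species
  structures (junction comparison, gradient distance matrix, 59-codon
  RSCU matrix, row/column dendrograms).

All outputs are single-header TSVs plus Newick dendrograms and a JSON
manifest; nothing in the result files depends on wall-clock time, so
reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .cds_io import CdsRecord, filter_cds, read_fasta, write_fasta
from .codon_pairs import (
    codon_pair_counts,
    junction_table,
    write_junction_tsv,
    write_rscpu_tsv,
)
from .comparative import (
    bicluster,
    build_rscu_matrix,
    gradient_distance_matrix,
    write_distance_tsv,
    write_merge_tsv,
    write_rscu_matrix_tsv,
)
from .composition import (
    composition_table,
    count_codons,
    gc3_gradient,
    write_composition_tsv,
    write_gradient_tsv,
)
from .enc_neutrality import (
    enc_table,
    neutrality_fit,
    write_enc_tsv,
    write_histogram_tsv,
    write_neutrality_tsv,
)
from .rscu import species_rscu, write_rscu_tsv
from .synthetic_data import generate_panel, spec_from_dict

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a pipeline run; defaults mirror the study design."""

    species: list[tuple[str, str]] = field(default_factory=list)
    min_len: int = 300
    gradient_mode: str = "positional"
    gradient_bins: int = 100
    rscu_threshold: float = 1.5
    freq_threshold: float = 0.60
    rscpu_threshold: float = 1.5
    pair_share_threshold: float = 0.60
    linkage: str = "complete"
    seed: int = 0
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [s for s, _ in self.species]
        if len(set(labels)) != len(labels):
            raise ValueError("species labels must be unique")
        if self.gradient_bins < 2:
            raise ValueError("gradient_bins must be >= 2")
        for t in (
            self.rscu_threshold,
            self.freq_threshold,
            self.rscpu_threshold,
            self.pair_share_threshold,
        ):
            if t <= 0:
                raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        species = [
            (entry["label"], entry["fasta"]) for entry in raw.pop("species", [])
        ]
        return cls(species=species, **raw)

    def to_dict(self) -> dict:
        return {
            "species": [{"label": l, "fasta": f} for l, f in self.species],
            "min_len": self.min_len,
            "gradient_mode": self.gradient_mode,
            "gradient_bins": self.gradient_bins,
            "rscu_threshold": self.rscu_threshold,
            "freq_threshold": self.freq_threshold,
            "rscpu_threshold": self.rscpu_threshold,
            "pair_share_threshold": self.pair_share_threshold,
            "linkage": self.linkage,
            "seed": self.seed,
            "simulate": self.simulate,
        }


def run_simulate(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the configured synthetic panel; one FASTA + sidecar per label."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = {
        label: spec_from_dict(cfg, seed=config.seed)
        for label, cfg in config.simulate.items()
    }
    if not specs:
        raise ValueError("no simulate entries in config")
    panel = generate_panel(specs)
    paths: dict[str, Path] = {}
    for label, records in panel.items():
        fasta = outdir / f"{label}.fa"
        write_fasta(records, fasta)
        sidecar = outdir / f"{label}.meta.json"
        sidecar.write_text(
            json.dumps(
                {"label": label, "seed": config.seed, "spec": config.simulate[label]},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        paths[label] = fasta
    return paths


def run_filter(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Filter each species' CDS file; write kept FASTA + per-rule report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for label, fasta in config.species:
        if not Path(fasta).exists():
            raise FileNotFoundError(f"species {label!r}: missing input {fasta}")
        records = read_fasta(fasta)
        kept, report = filter_cds(records, min_len=config.min_len)
        logger.info("%s: kept %d / %d CDSs", label, report.kept, report.total)
        report.to_tsv(outdir / f"{label}.filter_report.tsv")
        if kept:
            write_fasta(kept, outdir / f"{label}.filtered.fa")
        out[label] = outdir / f"{label}.filtered.fa"
    return out


def _profile_one(
    label: str, records: Sequence[CdsRecord], config: RunConfig, outdir: Path
):
    gene_counts = [count_codons(r) for r in records]
    comp = composition_table(records)
    write_composition_tsv(comp, outdir / f"{label}.composition.tsv")

    pooled, table = species_rscu(gene_counts, label)
    write_rscu_tsv(table, pooled, outdir / f"{label}.rscu.tsv")

    enc_records, hist = enc_table(records)
    write_enc_tsv(enc_records, outdir / f"{label}.enc.tsv")
    write_histogram_tsv(hist, outdir / f"{label}.enc_deviation_hist.tsv")

    gc12 = [(p.gc1 + p.gc2) / 2 for _, p in comp]
    gc3 = [p.gc3 for _, p in comp]
    fit = neutrality_fit(gc12, gc3)

    pairs = codon_pair_counts(records, scope=label)
    junction = junction_table(pairs)
    write_rscpu_tsv(pairs, outdir / f"{label}.rscpu.tsv")

    grad = gc3_gradient(
        records,
        n_bins=config.gradient_bins,
        mode=config.gradient_mode,  # type: ignore[arg-type]
        species=label,
    )
    write_gradient_tsv(grad, outdir / f"{label}.gc3_gradient.tsv")
    return table, fit, junction, grad


def run_profile(
    config: RunConfig,
    outdir: str | Path,
    inputs: Mapping[str, Sequence[CdsRecord]] | None = None,
) -> None:
    """Full per-species and cross-species profiling.

    ``inputs`` may supply already-filtered records per label; otherwise the
    configured FASTA paths are read and filtered first.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if inputs is None:
        inputs = {}
        for label, fasta in config.species:
            kept, _ = filter_cds(read_fasta(fasta), min_len=config.min_len)
            inputs[label] = kept

    tables, fits, junctions, gradients = [], [], {}, []
    for label, records in inputs.items():
        if not records:
            raise ValueError(f"species {label!r}: no records after filtering")
        try:
            table, fit, junction, grad = _profile_one(
                label, records, config, outdir
            )
        except Exception as exc:
            raise RuntimeError(f"profile stage failed for {label!r}: {exc}") from exc
        tables.append((label, table))
        fits.append((label, fit))
        junctions[label] = junction
        gradients.append(grad)

    write_neutrality_tsv(fits, outdir / "neutrality.tsv")
    write_junction_tsv(junctions, outdir / "junction_comparison.tsv")

    if len(tables) >= 2:
        dm = gradient_distance_matrix(gradients)
        write_distance_tsv(dm, outdir / "gc3_gradient_distances.tsv")
        matrix = build_rscu_matrix(tables)
        write_rscu_matrix_tsv(matrix, outdir / "rscu_matrix.tsv")
        row_d, col_d, row_order, col_order = bicluster(matrix)
        (outdir / "species_dendrogram.nwk").write_text(row_d.to_newick() + "\n")
        (outdir / "codon_dendrogram.nwk").write_text(col_d.to_newick() + "\n")
        write_merge_tsv(row_d, outdir / "species_merges.tsv")
        write_merge_tsv(col_d, outdir / "codon_merges.tsv")
        (outdir / "leaf_orders.json").write_text(
            json.dumps({"species": row_order, "codons": col_order}, indent=2)
            + "\n"
        )
    else:
        logger.info("single species: cross-species outputs skipped")

    manifest = {
        "package": "codonusage",
        "version": __version__,
        "config": config.to_dict(),
        "species_profiled": sorted(inputs),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
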