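"""Effective number of codons (ENc), the ENc plot and the neutrality plot.

Observed ENc is Wright's (1990) estimator. Per synonymous family with
amino-acid count n >= 2 and within-family frequencies p_j,

    F_hat = (n * sum(p_j^2) - 1) / (n - 1),

F_hat values are averaged within each degeneracy class k in {2, 3, 4, 6}
and

    ENc = 2 + 9 / F2 + 1 / F3 + 5 / F4 + 3 / F6,

capped at 61 (all synonyms equal) with a floor of 20 (one codon per amino
acid). If the 3-fold class (Ile) is unobserved, F3 is imputed as
(F2 + F4) / 2, following codonW; if any other class average is undefined
or zero the gene's ENc is undefined and the gene is excluded with a
logged reason.

The mutation-only expectation given the GC3s fraction F is

    ENc_exp = 2 + F + 29 / (F^2 + (1 - F)^2),

and the per-gene deviation statistic is (ENc_exp - ENc_obs) / ENc_exp;
genes on the curve give deviations near zero, genes under selective
constraint fall well below it (positive deviations).

The neutrality plot regresses per-gene GC12 = (GC1 + GC2)/2 on GC3 by
ordinary least squares; a slope near 1 indicates mutation pressure acting
equally on all positions, near 0 selective constraint on positions 1-2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .composition import CodonCountTable, count_codons, gc_profile
from .cds_io import CdsRecord
from .genetic_code import GeneticCode, standard_code

logger = logging.getLogger(__name__)

ENC_MIN = 20.0
ENC_MAX = 61.0

#: Table 2-style deviation histogram bin edges, half-open [lo, hi).
DEVIATION_BIN_EDGES = (-0.2, -0.1, 0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class EncRecord:
    """Per-gene observed/expected ENc and the deviation statistic."""

    gene_id: str
    enc_obs: float
    gc3s: float  # fraction in [0, 1]
    enc_exp: float
    deviation: float
    n_codons: int


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 with Pearson correlation and its p-value."""

    slope: float
    intercept: float
    r: float
    r2: float
    p_value: float
    n_genes: int


@dataclass(frozen=True)
class DeviationHistogram:
    """Percentages of genes per deviation bin plus an out-of-range count."""

    edges: tuple[float, ...]
    percentages: tuple[float, ...]
    out_of_range_pct: float
    n_genes: int


def enc_observed(
    counts: CodonCountTable, code: GeneticCode | None = None
) -> float | None:
    """Wright's ENc for one gene; ``None`` when undefined (gene excluded)."""
    code = code or standard_code()
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for k, aas in code.degeneracy_classes.items():
        if k == 1:
            continue
        for aa in aas:
            fam = code.families[aa]
            x = [counts.counts[c] for c in fam]
            n = sum(x)
            if n < 2:
                continue
            sum_p2 = sum((xi / n) ** 2 for xi in x)
            f_by_class[k].append((n * sum_p2 - 1) / (n - 1))
    f_bar: dict[int, float | None] = {
        k: (sum(v) / len(v) if v else None) for k, v in f_by_class.items()
    }
    if f_bar[3] is None and f_bar[2] is not None and f_bar[4] is not None:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2  # codonW-style Ile imputation
    weights = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}
    enc = 2.0
    for k, w in weights.items():
        fk = f_bar[k]
        if fk is None or fk == 0.0:
            logger.debug(
                "%s: ENc undefined (degeneracy class %d has no usable family)",
                counts.scope,
                k,
            )
            return None
        enc += w / fk
    return min(enc, ENC_MAX)


def enc_expected(gc3s: float) -> float:
    """Mutation-only expected ENc for GC3s fraction ``gc3s`` in [0, 1]."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"GC3s must be a fraction in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


def deviation_histogram(
    deviations: Sequence[float],
    edges: Sequence[float] = DEVIATION_BIN_EDGES,
) -> DeviationHistogram:
    """Histogram of deviation values over half-open [lo, hi) bins."""
    n = len(deviations)
    if n == 0:
        raise ValueError("no deviations to bin")
    edges = tuple(edges)
    counts = [0] * (len(edges) - 1)
    out = 0
    for d in deviations:
        if d < edges[0] or d >= edges[-1]:
            out += 1
            continue
        # rightmost bin whose lower edge <= d
        idx = int(np.searchsorted(edges, d, side="right")) - 1
        counts[idx] += 1
    return DeviationHistogram(
        edges=edges,
        percentages=tuple(100.0 * c / n for c in counts),
        out_of_range_pct=100.0 * out / n,
        n_genes=n,
    )


def enc_table(
    records: Sequence[CdsRecord], code: GeneticCode | None = None
) -> tuple[list[EncRecord], DeviationHistogram]:
    """Per-gene ENc records plus the binned deviation distribution.

    Genes with undefined ENc are excluded (logged with a count).
    """
    code = code or standard_code()
    out: list[EncRecord] = []
    excluded = 0
    for rec in records:
        counts = count_codons(rec)
        obs = enc_observed(counts, code)
        if obs is None:
            excluded += 1
            continue
        prof = gc_profile(counts, code)
        exp = enc_expected(prof.gc3s / 100.0)
        out.append(
            EncRecord(
                gene_id=rec.id,
                enc_obs=obs,
                gc3s=prof.gc3s / 100.0,
                enc_exp=exp,
                deviation=(exp - obs) / exp,
                n_codons=prof.n_codons,
            )
        )
    if excluded:
        logger.info("enc_table: %d gene(s) with undefined ENc excluded", excluded)
    if not out:
        raise ValueError("no gene with defined ENc")
    hist = deviation_histogram([r.deviation for r in out])
    return out, hist


def neutrality_fit(
    gc12: Sequence[float], gc3: Sequence[float]
) -> NeutralityFit:
    """OLS regression gc12 = intercept + slope * gc3 with Pearson r and p.

    Inputs are per-gene values (percent or fraction — the slope is unit
    free as long as both axes use the same scale).
    """
    gc12 = np.asarray(gc12, dtype=float)
    gc3 = np.asarray(gc3, dtype=float)
    if gc12.shape != gc3.shape or gc12.ndim != 1:
        raise ValueError("gc12 and gc3 must be 1-D arrays of equal length")
    if gc12.size < 3:
        raise ValueError("need at least 3 genes for a neutrality fit")
    if np.ptp(gc3) == 0.0:
        raise ValueError("zero variance in GC3: slope undefined")
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n_genes=int(gc12.size),
    )


def write_enc_tsv(records: Sequence[EncRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_codons\tGC3s\tENc_obs\tENc_exp\tdeviation\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.n_codons}\t{r.gc3s:.6f}\t{r.enc_obs:.4f}\t"
                f"{r.enc_exp:.4f}\t{r.deviation:.6f}\n"
            )


def write_histogram_tsv(hist: DeviationHistogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_lo\tbin_hi\tpercent\n")
        for lo, hi, pct in zip(hist.edges[:-1], hist.edges[1:], hist.percentages):
            fh.write(f"{lo:g}\t{hi:g}\t{pct:.4f}\n")
        fh.write(f"out_of_range\t\t{hist.out_of_range_pct:.4f}\n")


def write_neutrality_tsv(
    fits: Sequence[tuple[str, NeutralityFit]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("species\tslope\tintercept\tR2\tp\tn\n")
        for label, f in fits:
            fh.write(
                f"{label}\t{f.slope:.6f}\t{f.intercept:.6f}\t{f.r2:.6f}\t"
                f"{f.p_value:.3e}\t{f.n_genes}\n"
            )
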