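"""Seeded generator of valid CDS sets with controlled codon-usage structure.

The generator stands in for downloaded genomes: every emitted record is a
valid CDS (ATG start, single terminal stop, no ambiguity codes, no
internal stop, length > 300 nt) so the whole pipeline runs offline on
data whose codon-usage structure is known exactly.

Four codon-choice models are available:

``MutationOnly(theta)``
    Within each synonymous family, codons are weighted by independent
    per-position nucleotide probabilities restricted to the family;
    ``theta`` is the third-position G+C probability, positions 1-2 are
    uniform. Under this model third-position composition alone drives
    codon bias — the null hypothesis behind the mutation-only expected
    ENc curve. For a 2-fold T/C-ending family the expected RSCU of the
    C-ending codon is ``2 * theta``.

``Weighted(codon_weights)``
    Explicit within-family codon weights (map codon -> weight); models
    selection-like preferences and lets tests build species "clades".

``Gradient(theta_start, theta_end)``
    Like MutationOnly but theta varies linearly with codon position from
    5' to 3', producing a within-gene GC3 gradient.

``Coupled(slope, intercept, sigma, ...)``
    Per gene, a GC3 target is drawn uniformly from ``gc3_range`` and a
    GC12 target is set to ``intercept + slope * (gc3 - gc3_center) +
    N(0, sigma)``; codons are drawn from independent per-position
    nucleotide probabilities (positions 1-2 G+C = GC12 target, position 3
    G+C = GC3 target) with stop codons rejected. Emulates the linear
    GC12-GC3 coupling that a neutrality-plot regression measures.

``cg_suppression`` < 1 multiplies the sampling weight of the four NCG
codons (CG dinucleotide at positions 2-3), emulating the CpG avoidance
that depresses XCG/XCC ratios in plant genomes.

All randomness flows from a single integer seed; panels derive one
independent stream per species label so removing a label never perturbs
the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .cds_io import CdsRecord
from .genetic_code import STOP, STOP_CODONS, GeneticCode, standard_code

_GC = frozenset("GC")
_NCG = ("ACG", "CCG", "GCG", "TCG")


@dataclass(frozen=True)
class MutationOnly:
    theta: float  # third-position G+C probability

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0, 1)")


@dataclass(frozen=True)
class Weighted:
    codon_weights: Mapping[str, float]  # within-family weights, codon -> w >= 0


@dataclass(frozen=True)
class Gradient:
    theta_start: float
    theta_end: float

    def __post_init__(self) -> None:
        for t in (self.theta_start, self.theta_end):
            if not 0.0 < t < 1.0:
                raise ValueError("gradient endpoints must be in (0, 1)")


@dataclass(frozen=True)
class Coupled:
    slope: float
    intercept: float
    sigma: float
    gc3_range: tuple[float, float] = (0.25, 0.65)
    gc3_center: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.gc3_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("gc3_range must satisfy 0 < lo < hi < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


Model = Union[MutationOnly, Weighted, Gradient, Coupled]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic species' gene set."""

    n_genes: int
    codon_length_range: tuple[int, int]  # sense codons per gene, inclusive
    model: Model
    aa_weights: Mapping[str, float] | None = None  # default uniform over 20
    cg_suppression: float = 1.0
    stop_weights: Mapping[str, float] | None = None  # default uniform
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.codon_length_range
        if lo < 101 or hi < lo:
            raise ValueError(
                "codon_length_range must satisfy 101 <= min <= max "
                "(101 sense codons keeps every gene > 300 nt and long "
                "enough for a 100-bin positional gradient)"
            )
        if not 0.0 < self.cg_suppression <= 1.0:
            raise ValueError("cg_suppression must be in (0, 1]")


def _aa_distribution(
    spec: SyntheticSpec, code: GeneticCode
) -> tuple[list[str], np.ndarray]:
    aas = sorted(a for a in code.families if a != STOP)
    if spec.aa_weights is None:
        return aas, np.full(len(aas), 1.0 / len(aas))
    w = np.array([float(spec.aa_weights.get(a, 0.0)) for a in aas])
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("aa_weights must be non-negative and not all zero")
    return aas, w / w.sum()


def _stop_distribution(spec: SyntheticSpec) -> np.ndarray:
    if spec.stop_weights is None:
        return np.full(3, 1.0 / 3.0)
    w = np.array([float(spec.stop_weights.get(s, 0.0)) for s in STOP_CODONS])
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("stop_weights must be non-negative and not all zero")
    return w / w.sum()


def _third_base_split(fam: Sequence[str]) -> tuple[float, float]:
    """Normalizers for a family's third-position bases: the count of
    distinct G/C and distinct A/T third bases its codons offer."""
    bases = {c[2] for c in fam}
    return float(len(bases & _GC)), float(len(bases - _GC))


def _position_weight(codon: str, theta: float, fam: Sequence[str]) -> float:
    """Codon weight under the family-restricted mutation model.

    Positions 1-2 are uniform; the third-position G+C probability theta
    is split over the G/C bases the family actually offers (and 1-theta
    over its A/T bases), so P(third base in GC | family) = theta exactly
    for every degenerate family.
    """
    n_gc, n_at = _third_base_split(fam)
    if n_gc == 0:
        w3 = 1.0 / n_at
    elif n_at == 0:
        w3 = 1.0 / n_gc
    elif codon[2] in _GC:
        w3 = theta / n_gc
    else:
        w3 = (1.0 - theta) / n_at
    return 0.0625 * w3


def _family_weights(
    spec: SyntheticSpec, code: GeneticCode, theta: float | None
) -> dict[str, np.ndarray]:
    """Normalized within-family codon probabilities for theta-free or
    fixed-theta models."""
    out: dict[str, np.ndarray] = {}
    for aa, fam in code.families.items():
        if aa == STOP:
            continue
        if isinstance(spec.model, Weighted):
            w = np.array(
                [float(spec.model.codon_weights.get(c, 0.0)) for c in fam]
            )
        else:
            assert theta is not None
            w = np.array([_position_weight(c, theta, fam) for c in fam])
        w = w * np.array(
            [spec.cg_suppression if c in _NCG else 1.0 for c in fam]
        )
        if (w < 0).any() or w.sum() == 0:
            raise ValueError(f"infeasible codon weights for family {aa}")
        out[aa] = w / w.sum()
    return out


def _gene_family_model(
    spec: SyntheticSpec,
    code: GeneticCode,
    rng: np.random.Generator,
    length: int,
    aas: list[str],
    aa_p: np.ndarray,
) -> list[str]:
    """Draw one gene's sense codons for the family-restricted models."""
    aa_idx = rng.choice(len(aas), size=length - 1, p=aa_p)
    codons: list[str | None] = [None] * (length - 1)
    if isinstance(spec.model, Gradient):
        # theta varies with the codon's position along the gene
        pos = np.arange(1, length)  # codon 0 is the fixed ATG start
        thetas = spec.model.theta_start + (
            spec.model.theta_end - spec.model.theta_start
        ) * pos / max(length - 1, 1)
        for k, aa in enumerate(aas):
            sel = np.flatnonzero(aa_idx == k)
            if sel.size == 0:
                continue
            fam = code.families[aa]
            base = np.array(
                [spec.cg_suppression if c in _NCG else 1.0 for c in fam]
            ) * 0.0625
            third_gc = np.array([c[2] in _GC for c in fam])
            n_gc, n_at = _third_base_split(fam)
            th = thetas[sel][:, None]
            if n_gc == 0 or n_at == 0:
                w = np.broadcast_to(
                    base[None, :] / len(fam), (sel.size, len(fam))
                ).copy()
            else:
                w = base[None, :] * np.where(
                    third_gc[None, :], th / n_gc, (1 - th) / n_at
                )
            w /= w.sum(axis=1, keepdims=True)
            u = rng.random(sel.size)[:, None]
            pick = (w.cumsum(axis=1) < u).sum(axis=1)
            for s, j in zip(sel, pick):
                codons[s] = fam[j]
    else:
        theta = spec.model.theta if isinstance(spec.model, MutationOnly) else None
        fam_w = _family_weights(spec, code, theta)
        for k, aa in enumerate(aas):
            sel = np.flatnonzero(aa_idx == k)
            if sel.size == 0:
                continue
            fam = code.families[aa]
            picks = rng.choice(len(fam), size=sel.size, p=fam_w[aa])
            for s, j in zip(sel, picks):
                codons[s] = fam[j]
    return ["ATG"] + [c for c in codons]  # type: ignore[misc]


def _gene_coupled(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    length: int,
) -> list[str]:
    """Draw one gene's sense codons from the free-nucleotide coupled model."""
    m = spec.model
    assert isinstance(m, Coupled)
    gc3 = rng.uniform(*m.gc3_range)
    gc12 = m.intercept + m.slope * (gc3 - m.gc3_center) + rng.normal(0, m.sigma)
    gc12 = float(np.clip(gc12, 0.02, 0.98))

    def probs(gc: float) -> np.ndarray:
        # order A, C, G, T
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    bases = "ACGT"
    p12, p3 = probs(gc12), probs(gc3)
    need = length - 1
    codons: list[str] = []
    while len(codons) < need:
        k = (need - len(codons)) * 2 + 8  # oversample; rejection refills
        b1 = rng.choice(4, size=k, p=p12)
        b2 = rng.choice(4, size=k, p=p12)
        b3 = rng.choice(4, size=k, p=p3)
        keep_u = rng.random(k)
        for i in range(k):
            c = bases[b1[i]] + bases[b2[i]] + bases[b3[i]]
            if c in STOP_CODONS:
                continue
            if spec.cg_suppression < 1.0 and c in _NCG:
                if keep_u[i] >= spec.cg_suppression:
                    continue
            codons.append(c)
            if len(codons) == need:
                break
    return ["ATG"] + codons


def generate(
    spec: SyntheticSpec, label: str = "synth", code: GeneticCode | None = None
) -> list[CdsRecord]:
    """Generate ``spec.n_genes`` valid CDS records; deterministic per seed."""
    code = code or standard_code()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return _generate_with_rng(spec, label, code, rng)


def _generate_with_rng(
    spec: SyntheticSpec,
    label: str,
    code: GeneticCode,
    rng: np.random.Generator,
) -> list[CdsRecord]:
    aas, aa_p = _aa_distribution(spec, code)
    stop_p = _stop_distribution(spec)
    lo, hi = spec.codon_length_range
    records = []
    for g in range(spec.n_genes):
        length = int(rng.integers(lo, hi + 1))
        if isinstance(spec.model, Coupled):
            sense = _gene_coupled(spec, rng, length)
        else:
            sense = _gene_family_model(spec, code, rng, length, aas, aa_p)
        stop = STOP_CODONS[int(rng.choice(3, p=stop_p))]
        records.append(
            CdsRecord(id=f"{label}_g{g + 1:05d}", seq="".join(sense) + stop)
        )
    return records


def generate_panel(
    specs: Mapping[str, SyntheticSpec], code: GeneticCode | None = None
) -> dict[str, list[CdsRecord]]:
    """Generate one gene set per species label.

    Each label gets an independent random stream derived from
    ``(spec.seed, label)``, so panels are reproducible and removing or
    reordering labels leaves the other species' output unchanged.
    """
    code = code or standard_code()
    labels = list(specs)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species labels in panel")
    out: dict[str, list[CdsRecord]] = {}
    for label, spec in specs.items():
        ss = np.random.SeedSequence([spec.seed, *label.encode("utf-8")])
        rng = np.random.default_rng(ss)
        out[label] = _generate_with_rng(spec, label, code, rng)
    return out


def spec_from_dict(d: Mapping, seed: int | None = None) -> SyntheticSpec:
    """Build a SyntheticSpec from a plain (YAML-friendly) mapping."""
    d = dict(d)
    model_cfg = dict(d.pop("model"))
    kind = model_cfg.pop("kind")
    model_cls = {
        "mutation_only": MutationOnly,
        "weighted": Weighted,
        "gradient": Gradient,
        "coupled": Coupled,
    }
    if kind not in model_cls:
        raise ValueError(f"unknown model kind {kind!r}")
    if kind == "coupled" and "gc3_range" in model_cfg:
        model_cfg["gc3_range"] = tuple(model_cfg["gc3_range"])
    model = model_cls[kind](**model_cfg)
    if seed is not None:
        d["seed"] = seed
    d["codon_length_range"] = tuple(d["codon_length_range"])
    return SyntheticSpec(model=model, **d)
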