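"""Synthetic data with known ground truth for every pipeline stage.

Three generators cover the three structures the analysis assumes:
log2 expression vectors drawn from finite mixtures of normals (what the
mixture decomposition recovers), exact or noisy power-law rank-expression
vectors (what the Zipf test recovers), and tiny SAM+FASTA fixtures whose
per-locus base coverage is declared in a manifest (what the quantification
stage must reproduce bit-exactly). Every generator is a pure function of
its spec, including the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fungiflow.quantify import CoverageTable, ExpressionVector


@dataclass(frozen=True)
class MixtureSpec:
    """Ground-truth finite normal mixture in log2 expression space."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    variances: tuple[float, ...]
    n_genes: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.means) == len(self.variances)):
            raise ValueError("weights, means, variances must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(w <= 0 for w in self.weights):
            raise ValueError("mixture weights must be positive")
        if any(v <= 0 for v in self.variances):
            raise ValueError("variances must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    @property
    def K(self) -> int:
        return len(self.weights)

    def with_seed(self, seed: int) -> "MixtureSpec":
        return dataclasses.replace(self, seed=seed)


@dataclass(frozen=True)
class ZipfSpec:
    """Exact power law: expression of rank r is C * r^(-s), optionally noisy in log2."""

    exponent: float = 1.0
    constant: float = 1024.0
    n_genes: int = 5_000
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exponent <= 0 or self.constant <= 0:
            raise ValueError("exponent and constant must be positive")
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def with_seed(self, seed: int) -> "ZipfSpec":
        return dataclasses.replace(self, seed=seed)


@dataclass(frozen=True)
class ReadSpec:
    """One simulated read: its targets, full length, and clipping state."""

    read_id: str
    targets: tuple[str, ...]
    read_length: int = 50
    clipped: bool = False
    clip_length: int = 5

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("read must target at least one locus")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.clipped and not 0 < self.clip_length < self.read_length:
            raise ValueError("clip_length must be in (0, read_length)")


@dataclass(frozen=True)
class SamFixtureSpec:
    loci: tuple[tuple[str, int], ...]
    reads: tuple[ReadSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        tags = [t for t, _ in self.loci]
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate locus tags in fixture spec")
        if any(length < 1 for _, length in self.loci):
            raise ValueError("locus lengths must be >= 1")


@dataclass(frozen=True)
class SamFixture:
    """Generated fixture files plus the declared expected quantification."""

    fasta_text: str
    sam_text: str
    annotation: dict[str, int]
    expected: CoverageTable
    manifest: dict


@dataclass(frozen=True)
class Scenario:
    """A named spec plus the verdict the pipeline should reach on it."""

    name: str
    spec: MixtureSpec | ZipfSpec
    expected: dict


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_mixture(spec: MixtureSpec) -> tuple[ExpressionVector, np.ndarray]:
    """Draw a log2 expression vector from the spec's mixture.

    Returns the vector and the per-gene true component labels for
    recovery tests. Deterministic in the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(spec.K, size=spec.n_genes, p=np.asarray(spec.weights))
    means = np.asarray(spec.means)[labels]
    sds = np.sqrt(np.asarray(spec.variances))[labels]
    values = rng.normal(means, sds)
    series = pd.Series(values, index=_gene_names(spec.n_genes), name="log2_norm")
    return ExpressionVector(series), labels


def simulate_zipf(spec: ZipfSpec) -> ExpressionVector:
    """Power-law expression vector: log2 value of rank r is log2(C) - s*log2(r)."""
    ranks = np.arange(1, spec.n_genes + 1, dtype=float)
    values = np.log2(spec.constant) - spec.exponent * np.log2(ranks)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
    series = pd.Series(values, index=_gene_names(spec.n_genes), name="log2_norm")
    return ExpressionVector(series)


# ---------------------------------------------------------------------------
# SAM fixture generation


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _read_retained(read: ReadSpec) -> tuple[bool, str]:
    if len(set(read.targets)) > 1:
        return False, "multi_locus"
    if read.clipped:
        return False, "clipped"
    return True, "retained"


def generate_sam_fixture(spec: SamFixtureSpec) -> SamFixture:
    """Emit FASTA + SAM text and the expected coverage table.

    A clipped read is written with a soft-clip tail in its CIGAR; a
    multi-target read gets one primary plus secondary alignment lines.
    The manifest declares per read whether the full-length single-locus
    filter retains it, and per locus the expected raw base count.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = dict(spec.loci)

    fasta_lines = []
    sequences: dict[str, str] = {}
    for tag, length in spec.loci:
        seq = _random_sequence(rng, length)
        sequences[tag] = seq
        fasta_lines.append(f">{tag}")
        fasta_lines.extend(seq[i : i + 70] for i in range(0, length, 70))
    fasta_text = "\n".join(fasta_lines) + "\n"

    sam_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    sam_lines += [f"@SQ\tSN:{tag}\tLN:{length}" for tag, length in spec.loci]

    read_manifest = []
    bases = {tag: 0 for tag, _ in spec.loci}
    nreads = {tag: 0 for tag, _ in spec.loci}
    for read in spec.reads:
        for tag in read.targets:
            if tag not in lengths:
                raise ValueError(f"read {read.read_id!r} targets unknown locus {tag!r}")
            if read.read_length > lengths[tag]:
                raise ValueError(
                    f"read {read.read_id!r} ({read.read_length} bp) longer than locus "
                    f"{tag!r} ({lengths[tag]} bp)"
                )
        if read.clipped:
            aligned = read.read_length - read.clip_length
            cigar = f"{aligned}M{read.clip_length}S"
        else:
            aligned = read.read_length
            cigar = f"{read.read_length}M"
        seq = _random_sequence(rng, read.read_length)
        for i, tag in enumerate(read.targets):
            pos = int(rng.integers(1, lengths[tag] - aligned + 2))
            flag = 0 if i == 0 else 256
            mapq = 60 if i == 0 else 0
            sam_lines.append(
                "\t".join(
                    [
                        read.read_id,
                        str(flag),
                        tag,
                        str(pos),
                        str(mapq),
                        cigar,
                        "*",
                        "0",
                        "0",
                        seq,
                        "I" * read.read_length,
                    ]
                )
            )
        retained, reason = _read_retained(read)
        if retained:
            bases[read.targets[0]] += read.read_length
            nreads[read.targets[0]] += 1
        read_manifest.append(
            {
                "read_id": read.read_id,
                "targets": list(read.targets),
                "read_length": read.read_length,
                "clipped": read.clipped,
                "retained": retained,
                "reason": reason,
            }
        )
    sam_text = "\n".join(sam_lines) + "\n"

    frame = pd.DataFrame(
        {
            "raw_bases": pd.Series(bases, dtype=int),
            "n_reads": pd.Series(nreads, dtype=int),
            "length": pd.Series(lengths, dtype=int),
        }
    )
    frame.index.name = "locus_tag"
    expected = CoverageTable(frame)

    manifest = {
        "seed": spec.seed,
        "loci": {tag: length for tag, length in spec.loci},
        "reads": read_manifest,
        "expected_raw_bases": bases,
        "expected_n_reads": nreads,
        "total_bases": int(sum(bases.values())),
        "total_reads": int(sum(nreads.values())),
    }
    return SamFixture(
        fasta_text=fasta_text,
        sam_text=sam_text,
        annotation=lengths,
        expected=expected,
        manifest=manifest,
    )


def default_sam_fixture_spec(seed: int = 0) -> SamFixtureSpec:
    """Six-read fixture: three clean single-locus reads, two multi-locus, one clipped.

    The filter retains exactly the three clean reads: 2 x 50 bp on locusA
    and 1 x 50 bp on locusB, so the expected coverage is A=100, B=50.
    """
    return SamFixtureSpec(
        loci=(("locusA", 300), ("locusB", 200)),
        reads=(
            ReadSpec("r1", ("locusA",), 50),
            ReadSpec("r2", ("locusA",), 50),
            ReadSpec("r3", ("locusB",), 50),
            ReadSpec("r4", ("locusA", "locusB"), 50),
            ReadSpec("r5", ("locusB", "locusA"), 50),
            ReadSpec("r6", ("locusA",), 50, clipped=True),
        ),
        seed=seed,
    )


def two_class_sam_fixture_spec(
    n_low: int = 30,
    n_high: int = 30,
    read_length: int = 50,
    seed: int = 0,
) -> SamFixtureSpec:
    """Fixture with two well-separated expression classes for robustness checks.

    Low-class loci carry a handful of reads, high-class loci roughly fifty
    times as many, on loci of varying length, giving a clearly bimodal log2
    expression vector with every read retained by the filter.
    """
    rng = np.random.default_rng(seed)
    loci = []
    reads = []
    ridx = 0
    for cls, n_loci, lam in (("lo", n_low, 5.0), ("hi", n_high, 250.0)):
        for i in range(n_loci):
            tag = f"{cls}{i:03d}"
            length = int(rng.integers(200, 401))
            loci.append((tag, length))
            n_reads = int(rng.poisson(lam)) + 2
            for _ in range(n_reads):
                ridx += 1
                reads.append(ReadSpec(f"read{ridx:06d}", (tag,), read_length))
    return SamFixtureSpec(loci=tuple(loci), reads=tuple(reads), seed=seed)


# ---------------------------------------------------------------------------
# preset scenarios


def preset_scenarios() -> dict[str, Scenario]:
    """Named shape templates observed across fungal and metazoan datasets.

    Component means are separated by at least three within-component
    standard deviations so recovery at n=10,000 is comfortable rather than
    borderline.
    """
    scenarios = [
        Scenario(
            "unimodal",
            MixtureSpec(weights=(1.0,), means=(0.0,), variances=(1.0,)),
            {"n_peaks": 1, "n_main_peaks": 1, "label": "unimodal"},
        ),
        Scenario(
            # yeast-like: one predominant peak holding >= 70% of expressed genes
            "yeast_like",
            MixtureSpec(weights=(0.15, 0.85), means=(-3.0, 2.0), variances=(1.0, 1.0)),
            {
                "n_peaks": 2,
                "n_main_peaks": 2,
                "dominant_fraction_min": 0.70,
                "label": "bimodal",
            },
        ),
        Scenario(
            # metazoan-style bimodal: lowly- and highly-expressed gene classes
            "bimodal_metazoan",
            MixtureSpec(weights=(0.40, 0.60), means=(-4.0, 3.0), variances=(1.0, 1.0)),
            {"n_peaks": 2, "n_main_peaks": 2, "label": "bimodal", "zipf_consistent": False},
        ),
        Scenario(
            # filamentous-fungus-like: five components, three of them main
            "ncrassa_like",
            MixtureSpec(
                weights=(0.05, 0.30, 0.25, 0.30, 0.10),
                means=(-8.0, -4.0, 0.0, 4.0, 8.0),
                variances=(1.0, 1.0, 1.0, 1.0, 1.0),
            ),
            {"n_peaks": 5, "n_main_peaks": 3, "label": "multimodal"},
        ),
        Scenario(
            "zipf_s1",
            ZipfSpec(exponent=1.0, constant=1024.0, n_genes=5_000, noise_sd=0.0),
            {"gradient": -1.0, "zipf_consistent": True},
        ),
    ]
    return {s.name: s for s in scenarios}
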