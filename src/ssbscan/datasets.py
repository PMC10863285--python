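"""Dataset construction: positives with reverse-complement augmentation,
imbalanced negative sampling with an exclusion radius, dinucleotide-shuffled
negatives, and the leave-one-chromosome-out split.

The imbalance ratio Q sets the number of negatives to Q x (number of
positives).  Negatives are drawn uniformly over eligible window centers —
those at least ``exclusion_radius`` bp from every break site and far enough
from chromosome edges — and any window containing N is rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqcore import (
    GenomeSequence,
    GenomicSite,
    OutOfBoundsError,
    extract_context,
    reverse_complement,
)

logger = logging.getLogger(__name__)


class InfeasibleSamplingError(RuntimeError):
    """The eligible-center pool is too small for the requested negative count."""


class DegenerateSplitError(ValueError):
    """Either the train or the test side of a chromosome split is empty."""


@dataclass(frozen=True)
class DatasetConfig:
    flank: int = 125
    imbalance_ratio: int = 100
    strand_specific: bool = False
    exclusion_radius: int = 125
    test_chromosomes: frozenset[str] = frozenset({"chr1"})
    seed: int = 0
    negative_mode: str = "random_genome"

    def __post_init__(self) -> None:
        if self.imbalance_ratio < 1:
            raise ValueError("imbalance ratio Q must be >= 1")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")
        if self.negative_mode not in ("random_genome", "dinucleotide_shuffle"):
            raise ValueError(f"unknown negative_mode {self.negative_mode!r}")
        object.__setattr__(self, "test_chromosomes", frozenset(self.test_chromosomes))

    @property
    def window_length(self) -> int:
        return 2 * self.flank + 1


@dataclass(frozen=True)
class LabeledExample:
    sequence: str
    label: int
    chrom: str
    center_position: int
    origin: str  # positive | positive_rc | negative

    def __post_init__(self) -> None:
        if self.origin not in ("positive", "positive_rc", "negative"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if (self.label == 1) != (self.origin in ("positive", "positive_rc")):
            raise ValueError("label must be 1 exactly for positive origins")
        if "N" in self.sequence:
            raise ValueError("labeled examples must be N-free")


@dataclass
class SplitDataset:
    train: list[LabeledExample]
    test: list[LabeledExample]


@dataclass
class SkipReport:
    """Bookkeeping for sites dropped during positive-set construction."""

    out_of_bounds: int = 0
    contains_n: int = 0

    @property
    def total(self) -> int:
        return self.out_of_bounds + self.contains_n


def build_positive_set(
    genomes: Mapping[str, GenomeSequence],
    sites: Sequence[GenomicSite],
    config: DatasetConfig,
) -> tuple[list[LabeledExample], SkipReport]:
    """Extract labeled positive windows around break sites.

    Non-strand-specific mode emits two examples per usable site (the window and
    its reverse complement) — the augmentation appropriate for assays that do
    not resolve the nicked strand.  Strand-specific mode emits one example,
    reverse-complementing windows of minus-strand sites.  Sites whose window
    leaves the chromosome or contains N are skipped and tallied.
    """
    if not sites:
        logger.warning("empty site list: positive set is empty")
    examples: list[LabeledExample] = []
    report = SkipReport()
    for site in sites:
        if site.chrom not in genomes:
            raise KeyError(f"site chromosome {site.chrom!r} not in the genome set")
        try:
            window = extract_context(genomes[site.chrom], site, config.flank)
        except OutOfBoundsError:
            report.out_of_bounds += 1
            continue
        if "N" in window:
            report.contains_n += 1
            continue
        if config.strand_specific:
            seq = reverse_complement(window) if site.strand == "-" else window
            examples.append(LabeledExample(seq, 1, site.chrom, site.position, "positive"))
        else:
            examples.append(LabeledExample(window, 1, site.chrom, site.position, "positive"))
            examples.append(
                LabeledExample(reverse_complement(window), 1, site.chrom,
                               site.position, "positive_rc"))
    return examples, report


def _eligible_centers(
    genome: GenomeSequence,
    positive_positions: np.ndarray,
    flank: int,
    exclusion_radius: int,
) -> np.ndarray:
    """Centers whose window fits the chromosome and that clear every positive."""
    n = len(genome)
    if n < 2 * flank + 1:
        return np.empty(0, dtype=np.int64)
    mask = np.ones(n, dtype=bool)
    mask[:flank] = False
    mask[n - flank :] = False
    for pos in positive_positions:
        lo = max(0, int(pos) - exclusion_radius)
        hi = min(n, int(pos) + exclusion_radius + 1)
        mask[lo:hi] = False
    return np.nonzero(mask)[0]


def sample_negatives(
    genomes: Mapping[str, GenomeSequence],
    positive_sites: Sequence[GenomicSite],
    n_negatives: int,
    config: DatasetConfig,
) -> list[LabeledExample]:
    """Draw ``n_negatives`` label-0 windows uniformly over eligible centers.

    Eligibility: the full window fits on its chromosome and the center is at
    least ``exclusion_radius`` bp from every positive position.  Windows
    containing N are rejected and redrawn.  Reproducible under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    positions_by_chrom: dict[str, list[int]] = {name: [] for name in genomes}
    for site in positive_sites:
        if site.chrom in positions_by_chrom:
            positions_by_chrom[site.chrom].append(site.position)

    chrom_names = sorted(genomes)
    pools = []
    for name in chrom_names:
        centers = _eligible_centers(
            genomes[name], np.asarray(positions_by_chrom[name], dtype=np.int64),
            config.flank, config.exclusion_radius)
        pools.append(centers)
    pool_sizes = np.array([p.size for p in pools], dtype=np.int64)
    total = int(pool_sizes.sum())
    if total < n_negatives:
        raise InfeasibleSamplingError(
            f"eligible-center pool has {total} positions but {n_negatives} "
            "negatives were requested")

    offsets = np.concatenate([[0], np.cumsum(pool_sizes)])
    negatives: list[LabeledExample] = []
    taken: set[tuple[int, int]] = set()
    attempts = 0
    while len(negatives) < n_negatives:
        attempts += 1
        if attempts > 50 * n_negatives + 1000:
            raise InfeasibleSamplingError(
                "rejection sampling stalled (too many N-containing or duplicate windows)")
        flat = int(rng.integers(0, total))
        ci = int(np.searchsorted(offsets, flat, side="right") - 1)
        center = int(pools[ci][flat - offsets[ci]])
        if (ci, center) in taken:
            continue
        name = chrom_names[ci]
        window = genomes[name].residues[center - config.flank : center + config.flank + 1]
        if "N" in window:
            continue
        taken.add((ci, center))
        negatives.append(LabeledExample(window, 0, name, center, "negative"))
    return negatives


def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Shuffle preserving the exact multiset of overlapping dinucleotides.

    Euler-path shuffle: the sequence is a walk on the 4-vertex multigraph whose
    edges are its dinucleotides.  A uniformly chosen last-exit tree toward the
    terminal vertex fixes the final departure from each other vertex; remaining
    out-edges are permuted and the walk is replayed.  First and last residues
    are invariant.
    """
    if len(seq) < 2:
        raise ValueError("dinucleotide shuffle needs length >= 2")
    if any(c not in "ACGT" for c in seq):
        raise ValueError("dinucleotide shuffle is defined over A/C/G/T only")
    rng = np.random.default_rng(seed)
    vertices = sorted(set(seq))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]

    for _ in range(10000):
        # sample a candidate last-exit edge for every non-terminal vertex,
        # then verify those edges form a tree rooted at the terminal vertex
        last_exit: dict[str, str] = {}
        for v in vertices:
            if v != last and edges[v]:
                last_exit[v] = edges[v][int(rng.integers(0, len(edges[v])))]
        ok = True
        for v in last_exit:
            node, hops = v, 0
            while node != last:
                if node not in last_exit or hops > 8:
                    ok = False
                    break
                node = last_exit[node]
                hops += 1
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - the tree draw succeeds with probability >= 1/64
        raise RuntimeError("failed to draw a last-exit tree")

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        out = list(edges[v])
        if v in last_exit:
            out.remove(last_exit[v])
        rng.shuffle(out)
        if v in last_exit:
            out.append(last_exit[v])
        shuffled[v] = out

    result = [seq[0]]
    counters = {v: 0 for v in vertices}
    node = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[node][counters[node]]
        counters[node] += 1
        result.append(nxt)
        node = nxt
    return "".join(result)


def shuffle_negatives(
    positives: Sequence[LabeledExample], n_negatives: int, seed: int
) -> list[LabeledExample]:
    """Dinucleotide-shuffled versions of positive windows as label-0 examples."""
    rng = np.random.default_rng(seed)
    negatives: list[LabeledExample] = []
    i = 0
    while len(negatives) < n_negatives:
        src = positives[i % len(positives)]
        shuffled = dinucleotide_shuffle(src.sequence, int(rng.integers(0, 2**31 - 1)))
        negatives.append(
            LabeledExample(shuffled, 0, src.chrom, src.center_position, "negative"))
        i += 1
    return negatives


def split_leave_one_chromosome_out(
    examples: Sequence[LabeledExample], config: DatasetConfig
) -> SplitDataset:
    """Hold out all examples on ``config.test_chromosomes``; train on the rest."""
    test = [e for e in examples if e.chrom in config.test_chromosomes]
    train = [e for e in examples if e.chrom not in config.test_chromosomes]
    if not test or not train:
        raise DegenerateSplitError(
            f"split on {sorted(config.test_chromosomes)} leaves "
            f"{len(train)} train / {len(test)} test examples")
    return SplitDataset(train=train, test=test)


def build_dataset(
    genomes: Mapping[str, GenomeSequence],
    sites: Sequence[GenomicSite],
    config: DatasetConfig,
) -> tuple[SplitDataset, SkipReport]:
    """Positives + Q-fold negatives, split leave-one-chromosome-out.

    Negatives are sampled per split side so that |negatives| = Q x |positives|
    holds exactly within both train and test.
    """
    positives, report = build_positive_set(genomes, sites, config)
    pos_split = split_leave_one_chromosome_out(positives, config)

    def negatives_for(side: list[LabeledExample], genome_subset, offset: int):
        n_neg = config.imbalance_ratio * len(side)
        if config.negative_mode == "dinucleotide_shuffle":
            return shuffle_negatives(side, n_neg, config.seed + offset)
        side_cfg = DatasetConfig(**{**asdict(config), "seed": config.seed + offset,
                                    "test_chromosomes": config.test_chromosomes})
        return sample_negatives(genome_subset, sites, n_neg, side_cfg)

    train_genomes = {n: g for n, g in genomes.items() if n not in config.test_chromosomes}
    test_genomes = {n: g for n, g in genomes.items() if n in config.test_chromosomes}
    train = pos_split.train + negatives_for(pos_split.train, train_genomes, 1)
    test = pos_split.test + negatives_for(pos_split.test, test_genomes, 2)
    return SplitDataset(train=train, test=test), report


# ---------------------------------------------------------------------------
# Serialization: two-column TSV (sequence, label) + JSON provenance sidecar
# ---------------------------------------------------------------------------


def save_examples(examples: Sequence[LabeledExample], tsv_path: str | Path) -> None:
    tsv_path = Path(tsv_path)
    with open(tsv_path, "w") as fh:
        for ex in examples:
            fh.write(f"{ex.sequence}\t{ex.label}\n")
    sidecar = {
        "n_examples": len(examples),
        "provenance": [[ex.chrom, ex.center_position, ex.origin] for ex in examples],
    }
    with open(tsv_path.with_suffix(tsv_path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def load_examples(tsv_path: str | Path) -> list[LabeledExample]:
    tsv_path = Path(tsv_path)
    with open(tsv_path.with_suffix(tsv_path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    examples: list[LabeledExample] = []
    with open(tsv_path) as fh:
        for row, line in enumerate(fh):
            seq, label = line.rstrip("\n").split("\t")
            chrom, center, origin = sidecar["provenance"][row]
            examples.append(LabeledExample(seq, int(label), chrom, int(center), origin))
    return examples


def save_split(split: SplitDataset, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_examples(split.train, out_dir / "train.tsv")
    save_examples(split.test, out_dir / "test.tsv")


def load_split(out_dir: str | Path) -> SplitDataset:
    out_dir = Path(out_dir)
    return SplitDataset(
        train=load_examples(out_dir / "train.tsv"),
        test=load_examples(out_dir / "test.tsv"),
    )
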