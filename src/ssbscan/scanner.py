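"""Genome-wide sliding-window scoring, site calling, variant delta-landscapes,
and the cross-species landscape statistic.

A scan slides the model's 251 bp window along a chromosome and reports one
score per window center.  A species landscape samples a fixed number of
random windows from a genome (normalized sampling, so genome size does not
bias the count), counts those scoring above threshold as predicted break
sites, and pairs that count with the mean CpG content — across species the
two are compared with a Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .network import SSBModel
from .seqcore import GenomeSequence, GenomicSite, count_cpg, one_hot_encode


@dataclass
class ScoreTrack:
    """Per-center prediction scores over an interval of one chromosome."""

    chrom: str
    start: int  # 0-based start of the first window
    scores: np.ndarray
    stride: int = 1
    window: int = 251
    has_n: np.ndarray | None = None  # flags windows containing N

    @property
    def centers(self) -> np.ndarray:
        half = self.window // 2
        return self.start + half + self.stride * np.arange(len(self.scores))


@dataclass(frozen=True)
class SpeciesLandscape:
    species: str
    n_windows: int
    ssb_count: int
    mean_cpg: float

    def __post_init__(self) -> None:
        if not (0 <= self.ssb_count <= self.n_windows):
            raise ValueError("ssb_count must lie in [0, n_windows]")
        if self.mean_cpg < 0:
            raise ValueError("mean_cpg must be non-negative")


def n_windows(length: int, window: int = 251, stride: int = 1) -> int:
    """Closed-form window count: floor((length - window)/stride) + 1."""
    return (length - window) // stride + 1


def scan_sequence(model: SSBModel, genome: GenomeSequence, stride: int = 1,
                  start: int = 0, end: int | None = None,
                  batch_size: int = 512) -> ScoreTrack:
    """Score every window of ``genome.residues[start:end]`` at the given stride.

    Windows containing N are still scored (their N columns encode to zero) and
    flagged in the output track.
    """
    window = model.config.full_length
    end = len(genome) if end is None else end
    seq = genome.residues[start:end]
    if len(seq) < window:
        raise ValueError(
            f"region of length {len(seq)} is shorter than the {window} bp window")
    enc = one_hot_encode(seq).matrix  # 4 x L
    views = np.lib.stride_tricks.sliding_window_view(enc, window, axis=1)
    views = views[:, ::stride, :]  # (4, n_out, window)
    n_out = views.shape[1]
    scores = np.empty(n_out, dtype=np.float32)
    for lo in range(0, n_out, batch_size):
        batch = np.ascontiguousarray(
            views[:, lo : lo + batch_size, :].transpose(1, 0, 2))
        scores[lo : lo + batch.shape[0]] = model.predict(batch, batch_size=batch_size)
    col_sums = enc.sum(axis=0)
    has_n_pos = col_sums == 0
    window_has_n = (np.convolve(has_n_pos, np.ones(window), mode="valid") > 0)[::stride]
    return ScoreTrack(genome.name, start, scores, stride, window, window_has_n)


def call_putative_sites(track: ScoreTrack, threshold: float = 0.5) -> list[GenomicSite]:
    """Window centers scoring >= threshold, as sorted 0-based sites."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    centers = track.centers[track.scores >= threshold]
    return [GenomicSite(track.chrom, int(c)) for c in np.sort(centers)]


@dataclass
class VariantDelta:
    """Reference and alternate score tracks around a SNP, plus their difference."""

    ref_track: ScoreTrack
    alt_track: ScoreTrack
    delta: np.ndarray
    variant: tuple[str, int, str, str]


def variant_delta_track(model: SSBModel, genome: GenomeSequence,
                        chrom: str, pos: int, ref: str, alt: str) -> VariantDelta:
    """Score change caused by a single-base substitution.

    Scans the region centered on ``pos`` wide enough to cover every window
    overlapping the variant; windows not containing ``pos`` have delta exactly 0.
    """
    if genome.name != chrom:
        raise ValueError(f"variant chromosome {chrom!r} != genome {genome.name!r}")
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only single-base substitutions are supported")
    observed = genome.residues[pos]
    if observed != ref:
        raise ValueError(
            f"reference check failed at {chrom}:{pos}: genome has {observed!r}, "
            f"variant says {ref!r}")
    window = model.config.full_length
    start = max(0, pos - (window - 1))
    end = min(len(genome), pos + window)
    ref_track = scan_sequence(model, genome, start=start, end=end)
    alt_residues = genome.residues[:pos] + alt + genome.residues[pos + 1 :]
    alt_genome = GenomeSequence(genome.name, alt_residues)
    alt_track = scan_sequence(model, alt_genome, start=start, end=end)
    delta = alt_track.scores - ref_track.scores
    return VariantDelta(ref_track, alt_track, delta, (chrom, pos, ref, alt))


def normalized_genome_sampling(genome: GenomeSequence, n: int = 1_000_000,
                               L: int = 251, seed: int = 0) -> tuple[np.ndarray, list[str]]:
    """Draw ``n`` random L bp windows (uniform over valid starts, N-free).

    Returns (start positions, window sequences).  Windows containing N are
    resampled so every species contributes the same number of scoreable
    windows regardless of genome size or N content.
    """
    if len(genome) < L:
        raise ValueError(f"chromosome {genome.name} shorter than {L} bp")
    rng = np.random.default_rng(seed)
    max_start = len(genome) - L
    starts = np.empty(n, dtype=np.int64)
    seqs: list[str] = []
    filled = 0
    attempts = 0
    while filled < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise RuntimeError("sampling stalled: too many N-containing windows")
        s = int(rng.integers(0, max_start + 1))
        w = genome.residues[s : s + L]
        if "N" in w:
            continue
        starts[filled] = s
        seqs.append(w)
        filled += 1
    return starts, seqs


def build_species_landscape(model: SSBModel, genome: GenomeSequence, species: str,
                            n: int = 1000, seed: int = 0,
                            threshold: float = 0.5) -> SpeciesLandscape:
    """Sample windows, score them, and summarize break propensity vs CpG content."""
    L = model.config.full_length
    _, seqs = normalized_genome_sampling(genome, n=n, L=L, seed=seed)
    X = np.stack([one_hot_encode(s).matrix for s in seqs])
    scores = model.predict(X)
    ssb_count = int((scores >= threshold).sum())
    mean_cpg = float(np.mean([count_cpg(s) for s in seqs]))
    return SpeciesLandscape(species, n, ssb_count, mean_cpg)


def cpg_ssb_correlation(landscapes: Sequence[SpeciesLandscape]) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of mean CpG content vs break count."""
    if len(landscapes) < 3:
        raise ValueError("need at least 3 species")
    x = np.array([l.mean_cpg for l in landscapes], dtype=np.float64)
    y = np.array([l.ssb_count for l in landscapes], dtype=np.float64)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance in CpG content or break counts")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def write_landscape_tsv(landscapes: Sequence[SpeciesLandscape], path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tn_windows\tssb_count\tmean_cpg\n")
        for ls in landscapes:
            fh.write(f"{ls.species}\t{ls.n_windows}\t{ls.ssb_count}\t{ls.mean_cpg:.6f}\n")
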