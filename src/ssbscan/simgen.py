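"""Synthetic genomes with planted break sites.

The generator writes an i.i.d. background genome with human-like base
composition (0.3, 0.2, 0.2, 0.3 over A, C, G, T), then plants break sites
carrying the two sequence signals the classifier is meant to detect: a GGC
trinucleotide whose middle base sits exactly on the break coordinate, and
CpG-enriched flanks within +/-50 bp.  Site coordinates are emitted as a
summit BED together with a truth table, so every downstream module can be
exercised without any external download.

The defaults (1 Mb over two chromosomes, 2,000 sites, motif strength 1,
3-fold CpG enrichment) define the benchmark conditions used by the test
suite; they are fixture parameters, not biological claims.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .datasets import DatasetConfig, SkipReport, SplitDataset, build_dataset
from .seqcore import (
    GenomeSequence,
    GenomicSite,
    count_cpg,
    write_bed_sites,
    write_fasta,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 1_000_000  # total, split over n_chromosomes
    n_chromosomes: int = 2
    composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    n_sites: int = 2_000
    motif: str = "GGC"
    motif_strength: float = 1.0
    cpg_enrichment: float = 3.0
    cpg_range: int = 50  # enrichment applied within +/- this many bp of a site
    min_site_spacing: int = 250
    edge_margin: int = 125  # sites stay this far from chromosome ends
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must lie in [0, 1]")
        if self.cpg_enrichment < 1.0:
            raise ValueError("cpg_enrichment must be >= 1")
        if self.n_sites * self.min_site_spacing >= self.genome_length:
            raise ValueError("sites at this spacing do not fit the genome")
        if self.n_chromosomes < 2:
            raise ValueError("need >= 2 chromosomes so a held-out split exists")

    def chromosome_lengths(self) -> dict[str, int]:
        base = self.genome_length // self.n_chromosomes
        lengths = {f"chr{i + 1}": base for i in range(self.n_chromosomes)}
        lengths[f"chr{self.n_chromosomes}"] += self.genome_length - base * self.n_chromosomes
        return lengths


def _random_residues(rng: np.random.Generator, n: int,
                     composition: tuple[float, ...]) -> np.ndarray:
    return _BASES[rng.choice(4, size=n, p=np.asarray(composition, dtype=np.float64))]


def generate_background_genome(config: SimConfig) -> dict[str, GenomeSequence]:
    """i.i.d. background chromosomes from the configured base composition."""
    rng = np.random.default_rng(config.seed)
    genomes: dict[str, GenomeSequence] = {}
    for name, length in config.chromosome_lengths().items():
        residues = _random_residues(rng, length, config.composition)
        genomes[name] = GenomeSequence(name, residues.tobytes().decode("ascii"))
    return genomes


def _spaced_positions(rng: np.random.Generator, n: int, lo: int, hi: int,
                      spacing: int) -> np.ndarray:
    """n sorted positions in [lo, hi] with all pairwise gaps >= spacing."""
    slack = (hi - lo) - (n - 1) * spacing
    if slack < 0:
        raise ValueError("infeasible site placement: not enough room at this spacing")
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    return lo + offsets + spacing * np.arange(n)


def _tilted_segment(rng: np.random.Generator, length: int,
                    composition: tuple[float, ...], enrichment: float,
                    candidates: int = 24) -> np.ndarray:
    """Importance-resampled i.i.d. segment, tilted toward higher CpG count.

    Draws ``candidates`` i.i.d. segments and picks one with probability
    proportional to enrichment^(CpG count) — a multiplicative tilt on the CG
    dinucleotide frequency at exact segment length.
    """
    pool = _BASES[rng.choice(4, size=(candidates, length),
                             p=np.asarray(composition, dtype=np.float64))]
    cg = ((pool[:, :-1] == ord("C")) & (pool[:, 1:] == ord("G"))).sum(axis=1)
    w = enrichment ** cg.astype(np.float64)
    return pool[rng.choice(candidates, p=w / w.sum())]


def plant_positive_sites(
    genomes: Mapping[str, GenomeSequence], config: SimConfig
) -> tuple[dict[str, GenomeSequence], list[GenomicSite], list[dict]]:
    """Plant break sites into background chromosomes.

    Returns the modified genomes, the site list (summit convention), and a
    truth record per site (chromosome, position, whether the motif was written,
    flank CpG count after enrichment).
    """
    rng = np.random.default_rng(config.seed + 1)
    lengths = {name: len(g) for name, g in genomes.items()}
    total = sum(lengths.values())
    names = sorted(genomes)
    # allocate site counts proportionally to chromosome length
    counts = {name: int(round(config.n_sites * lengths[name] / total)) for name in names}
    drift = config.n_sites - sum(counts.values())
    counts[names[0]] += drift

    motif = np.frombuffer(config.motif.encode("ascii"), dtype=np.uint8)
    half_m = (len(motif) - 1) // 2
    modified: dict[str, GenomeSequence] = {}
    sites: list[GenomicSite] = []
    truth: list[dict] = []
    for name in names:
        arr = np.frombuffer(genomes[name].residues.encode("ascii"),
                            dtype=np.uint8).copy()
        n_here = counts[name]
        if n_here == 0:
            modified[name] = genomes[name]
            continue
        positions = _spaced_positions(
            rng, n_here, config.edge_margin,
            lengths[name] - 1 - config.edge_margin, config.min_site_spacing)
        for pos in positions:
            pos = int(pos)
            # CpG-enriched flanks on both sides of the motif span
            left_lo = max(0, pos - config.cpg_range)
            left_hi = pos - half_m
            right_lo = pos - half_m + len(motif)
            right_hi = min(lengths[name], pos + config.cpg_range + 1)
            if config.cpg_enrichment > 1.0:
                arr[left_lo:left_hi] = _tilted_segment(
                    rng, left_hi - left_lo, config.composition, config.cpg_enrichment)
                arr[right_lo:right_hi] = _tilted_segment(
                    rng, right_hi - right_lo, config.composition, config.cpg_enrichment)
            planted = bool(rng.random() < config.motif_strength)
            if planted:
                arr[pos - half_m : pos - half_m + len(motif)] = motif
            flank = arr[pos - config.cpg_range : pos + config.cpg_range + 1]
            sites.append(GenomicSite(name, pos))
            truth.append({
                "chrom": name,
                "position": pos,
                "motif_planted": planted,
                "flank_cpg": int(count_cpg(flank.tobytes().decode("ascii"))),
            })
        modified[name] = GenomeSequence(name, arr.tobytes().decode("ascii"))
    return modified, sites, truth


@dataclass
class BenchmarkBundle:
    genomes: dict[str, GenomeSequence]
    sites: list[GenomicSite]
    truth: list[dict]
    split: SplitDataset
    skip_report: SkipReport


def generate_benchmark_bundle(
    sim_config: SimConfig,
    dataset_config: DatasetConfig,
    out_dir: str | Path | None = None,
) -> BenchmarkBundle:
    """Genome + sites + labeled train/test split, optionally written to disk.

    Deterministic under (SimConfig.seed, DatasetConfig.seed): regenerating
    with the same configuration reproduces byte-identical FASTA/BED output.
    """
    background = generate_background_genome(sim_config)
    genomes, sites, truth = plant_positive_sites(background, sim_config)
    split, report = build_dataset(genomes, sites, dataset_config)
    bundle = BenchmarkBundle(genomes, sites, truth, split, report)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(genomes, out_dir / "genome.fa")
        write_bed_sites(sites, out_dir / "sites.bed")
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write("chrom\tposition\tmotif_planted\tflank_cpg\n")
            for rec in truth:
                fh.write(f"{rec['chrom']}\t{rec['position']}\t"
                         f"{int(rec['motif_planted'])}\t{rec['flank_cpg']}\n")
    return bundle
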