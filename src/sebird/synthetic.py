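"""Synthetic genomes with planted super-enhancer / typical-enhancer regions.

The generator emulates the statistical structure of real SE/TE interval
collections without any downloads: a random i.i.d. genome at a chosen GC
content, long motif-enriched SE regions (log-normal lengths, median
~8 kb, clipped to 2.5-25 kb), short weakly-enriched TE regions (median
~0.8 kb), and decoy open-reading-frame annotation used to exercise
flank-overlap filtering. The class signal is a motif-density difference:
transcription-factor-binding-site-like k-mers are written into SE
regions at a higher per-kb density than TE regions. Setting the two
densities equal produces a null fixture with no sequence signal at all,
which is the negative-control configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .intervals import LABEL_SE, LABEL_TE, Genome, GenomicInterval, write_bed

_STOP_CODONS = {"TAA", "TAG", "TGA"}

# Defaults mimic well-known TFBS cores (AP-1, NF-kB-like, E-box, OCT-like);
# the exact strings only need to be distinguishable from background.
DEFAULT_SE_MOTIFS = ("TGACTCAA", "GGGACTTTCC")
DEFAULT_TE_MOTIFS = ("CACGTGAC", "ATGCAAAT")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cell-line fixture."""

    genome_length: int = 12_000_000
    gc_content: float = 0.41
    n_se: int = 200
    n_te: int = 200
    # log-normal length models; medians in bp
    se_length_median: float = 8_000.0
    se_length_sigma: float = 0.55
    se_length_min: int = 2_500
    se_length_max: int = 25_000
    te_length_median: float = 800.0
    te_length_sigma: float = 0.45
    te_length_min: int = 200
    te_length_max: int = 2_400
    se_motifs: tuple[str, ...] = DEFAULT_SE_MOTIFS
    te_motifs: tuple[str, ...] = DEFAULT_TE_MOTIFS
    se_motif_density: float = 10.0  # motifs per kb
    te_motif_density: float = 2.0
    n_orf_decoys: int = 20
    orf_decoy_length: int = 300
    chrom_name: str = "chr1"
    # flank augmentation grows TEs to SE-like lengths (~8 kb); regions
    # need room so extended windows rarely collide with their neighbours
    min_gap: int = 3_000
    seed: int = 0

    def null_signal(self) -> "SyntheticSpec":
        """A copy with equal motif content in both classes (no signal)."""
        return replace(
            self,
            se_motifs=self.te_motifs,
            se_motif_density=self.te_motif_density,
        )


def generate_genome(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> Genome:
    """An i.i.d. random genome at the requested GC content."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = codes[rng.choice(4, size=spec.genome_length, p=p)].tobytes().decode()
    return Genome({spec.chrom_name: seq})


@dataclass
class PlantedFixture:
    genome: Genome
    se_intervals: list[GenomicInterval]
    te_intervals: list[GenomicInterval]
    annotation: list[GenomicInterval] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.to_fasta(outdir / "genome.fa")
        write_bed(self.se_intervals, outdir / "se.bed")
        write_bed(self.te_intervals, outdir / "te.bed")
        write_bed(self.annotation, outdir / "annotation.bed")


def _draw_lengths(
    rng: np.random.Generator, n: int, median: float, sigma: float,
    lo: int, hi: int,
) -> np.ndarray:
    lengths = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
    return np.clip(np.round(lengths), lo, hi).astype(int)


def _place_non_overlapping(
    rng: np.random.Generator, lengths: np.ndarray, genome_length: int, min_gap: int
) -> np.ndarray:
    """Random non-overlapping starts with >= min_gap spacing, uniform slack."""
    n = len(lengths)
    occupied = int(lengths.sum()) + min_gap * (n + 1)
    free = genome_length - occupied
    if free < 0:
        raise ValueError(
            f"genome of {genome_length} bp too small for {n} regions "
            f"totalling {occupied} bp incl. gaps"
        )
    # split the free space uniformly among the n+1 inter-region gaps
    cuts = np.sort(rng.integers(0, free + 1, size=n))
    slack = np.diff(np.concatenate(([0], cuts)))
    starts = np.empty(n, dtype=int)
    pos = min_gap
    for i in range(n):
        pos += slack[i]
        starts[i] = pos
        pos += lengths[i] + min_gap
    return starts


def _plant_motifs(
    chrom: np.ndarray, iv: GenomicInterval, motifs: tuple[str, ...],
    density_per_kb: float, rng: np.random.Generator,
) -> None:
    n_sites = int(round(density_per_kb * iv.length() / 1000.0))
    if n_sites == 0 or not motifs:
        return
    max_mlen = max(len(m) for m in motifs)
    if iv.length() <= max_mlen:
        return
    # non-overlapping placement by sampling distinct slots
    slot = max_mlen
    n_slots = iv.length() // slot
    n_sites = min(n_sites, n_slots)
    chosen = rng.choice(n_slots, size=n_sites, replace=False)
    for s in chosen:
        motif = motifs[rng.integers(len(motifs))]
        offset = iv.start + int(s) * slot
        chrom[offset : offset + len(motif)] = np.frombuffer(motif.encode(), np.uint8)


def _random_orf(length: int, rng: np.random.Generator) -> str:
    """ATG followed by stop-free codons, ending in a stop codon."""
    n_codons = max(length // 3, 3)
    codons = ["ATG"]
    bases = "ACGT"
    while len(codons) < n_codons - 1:
        codon = "".join(bases[rng.integers(4)] for _ in range(3))
        if codon not in _STOP_CODONS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def plant_regions(
    genome: Genome, spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> PlantedFixture:
    """Plant SE/TE regions and ORF decoys; returns the modified fixture.

    Half of the ORF decoys are deliberately placed a short distance after
    a TE so that flank-extended TE windows can run into them, exercising
    the annotation-overlap exclusion step downstream.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    chrom_name = spec.chrom_name
    chrom = np.frombuffer(genome[chrom_name].encode(), dtype=np.uint8).copy()
    genome_length = len(chrom)

    se_lengths = _draw_lengths(
        rng, spec.n_se, spec.se_length_median, spec.se_length_sigma,
        spec.se_length_min, spec.se_length_max,
    )
    te_lengths = _draw_lengths(
        rng, spec.n_te, spec.te_length_median, spec.te_length_sigma,
        spec.te_length_min, spec.te_length_max,
    )
    all_lengths = np.concatenate([se_lengths, te_lengths])
    # shuffle SE/TE order along the chromosome
    order = rng.permutation(len(all_lengths))
    starts_ordered = _place_non_overlapping(
        rng, all_lengths[order], genome_length, spec.min_gap
    )
    starts = np.empty_like(starts_ordered)
    starts[order] = starts_ordered

    se_ivs = [
        GenomicInterval(chrom_name, int(s), int(s + l), label=LABEL_SE,
                        name=f"SE:{i}")
        for i, (s, l) in enumerate(zip(starts[: spec.n_se], se_lengths))
    ]
    te_ivs = [
        GenomicInterval(chrom_name, int(s), int(s + l), label=LABEL_TE,
                        name=f"TE:{i}")
        for i, (s, l) in enumerate(zip(starts[spec.n_se :], te_lengths))
    ]

    for iv in se_ivs:
        _plant_motifs(chrom, iv, spec.se_motifs, spec.se_motif_density, rng)
    for iv in te_ivs:
        _plant_motifs(chrom, iv, spec.te_motifs, spec.te_motif_density, rng)

    annotation: list[GenomicInterval] = []
    n_adjacent = spec.n_orf_decoys // 2
    te_for_decoys = rng.choice(len(te_ivs), size=min(n_adjacent, len(te_ivs)),
                               replace=False)
    planted = sorted([(iv.start, iv.end) for iv in se_ivs + te_ivs])

    def _free(s: int, e: int) -> bool:
        import bisect
        i = bisect.bisect_right(planted, (s, s)) - 1
        for j in (i, i + 1):
            if 0 <= j < len(planted) and planted[j][0] < e and s < planted[j][1]:
                return False
        return True

    for ti in te_for_decoys:
        te = te_ivs[int(ti)]
        s = te.end + spec.min_gap // 4  # inside the flanking zone
        e = s + spec.orf_decoy_length
        if e <= genome_length and _free(s, e):
            orf = _random_orf(spec.orf_decoy_length, rng)
            chrom[s : s + len(orf)] = np.frombuffer(orf.encode(), np.uint8)
            annotation.append(GenomicInterval(chrom_name, s, s + len(orf),
                                              name="ORF"))
    attempts = 0
    while len(annotation) < spec.n_orf_decoys and attempts < 10_000:
        attempts += 1
        s = int(rng.integers(0, genome_length - spec.orf_decoy_length))
        e = s + spec.orf_decoy_length
        if _free(s, e):
            orf = _random_orf(spec.orf_decoy_length, rng)
            chrom[s : s + len(orf)] = np.frombuffer(orf.encode(), np.uint8)
            annotation.append(GenomicInterval(chrom_name, s, s + len(orf),
                                              name="ORF"))

    mutated = Genome({chrom_name: chrom.tobytes().decode()})
    return PlantedFixture(mutated, se_ivs, te_ivs, annotation)


def make_fixture(spec: SyntheticSpec) -> PlantedFixture:
    """Genome generation + region planting under one seed."""
    rng = np.random.default_rng(spec.seed)
    genome = generate_genome(spec, rng)
    return plant_regions(genome, spec, rng)
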