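"""Synthetic data: Ct generation, qPCR plates, and a two-species genome pair.

The Ct model is the exponential-amplification closed form: a well seeded
with ``c`` copies crosses threshold at ``ct_single_copy - log_{1+E}(c)``
cycles plus Gaussian noise, censored at the final cycle. Copies are
integers; a zero-copy well never amplifies. Ct depends only on target
copies (one assay locus per haploid genome), not on genome length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_io import GenomeSequence

__all__ = [
    "SimulationConfig",
    "SyntheticGenomeSpec",
    "GenomePair",
    "simulate_ct",
    "simulate_plate",
    "mixture_series",
    "synthetic_genome_pair",
    "MIXTURE_FRACTIONS",
    "SENSITIVITY_FRACTIONS",
    "DEFAULT_TOTAL_COPIES",
]

#: Efficiency-test design: pure endpoints plus 75/25, 50/50, 25/75 mixes
#: of 5,000 total genome copies.
MIXTURE_FRACTIONS = (1.0, 0.75, 0.5, 0.25, 0.0)
#: Sensitivity-test design: the smallest component is 50 copies (1%).
SENSITIVITY_FRACTIONS = (0.99, 0.9, 0.5, 0.1, 0.01)
DEFAULT_TOTAL_COPIES = 5000

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the Ct generator."""

    efficiency: float = 1.0  # per-cycle amplification gain E; 1.0 = doubling
    ct_single_copy: float = 38.0  # intercept: expected Ct of one copy
    noise_sd: float = 0.15  # cycles
    censor_cycle: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ct_single_copy > self.censor_cycle:
            raise ValueError("ct_single_copy must not exceed censor_cycle")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Blueprint for a designable two-species gene locus.

    Exons are near-identical between the species (conserved coding
    sequence); introns diverge according to ``intron_identity``. Layout:
    flank, exon1, intron1, exon2, ..., exonN, flank.
    """

    exon_lengths: tuple[int, ...] = (120, 100, 110, 90, 130)
    intron_lengths: tuple[int, ...] = (400, 420, 380, 410)
    exon_identity: float = 0.95
    intron_identity: float = 0.4
    flank_length: int = 300
    min_primer_len: int = 25
    gene_id: str = "geneA"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.exon_lengths) < 3:
            raise ValueError("need at least 3 exons")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one intron between consecutive exons")
        floor = self.min_primer_len + 10
        if any(l < floor for l in self.intron_lengths):
            raise ValueError(
                f"infeasible spec: every intron must be >= {floor} nt to host a primer"
            )
        for name in ("exon_identity", "intron_identity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class GenomePair:
    genome_a: GenomeSequence
    genome_b: GenomeSequence
    gff_a: str
    gff_b: str
    gene_id: str
    exon_starts: tuple[int, ...] = field(default=())


def simulate_ct(
    copies: int,
    config: SimulationConfig = SimulationConfig(),
    rng: np.random.Generator | None = None,
) -> float | None:
    """One well's Ct for an integer copy count; None when censored."""
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if int(copies) != copies:
        raise ValueError("copies must be an integer count")
    if copies == 0:
        return None
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ct = config.ct_single_copy - math.log(copies, 1.0 + config.efficiency)
    if config.noise_sd > 0:
        ct += rng.normal(0.0, config.noise_sd)
    return None if ct > config.censor_cycle else float(ct)


def simulate_plate(
    h_copies: int,
    m_copies: int,
    n_replicates: int = 3,
    config: SimulationConfig = SimulationConfig(),
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Independent noisy wells for each assay x replicate.

    Returns a table with columns sample_id, assay, replicate, ct;
    censored wells carry NaN Ct. Same config (incl. seed) reproduces
    the table exactly.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(config.seed)
    rows = []
    for assay, copies in (("human", h_copies), ("mouse", m_copies)):
        for rep in range(1, n_replicates + 1):
            ct = simulate_ct(copies, config, rng)
            rows.append(
                {
                    "sample_id": sample_id,
                    "assay": assay,
                    "replicate": rep,
                    "ct": math.nan if ct is None else ct,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "assay", "replicate", "ct"])


def mixture_series(
    total_copies: int = DEFAULT_TOTAL_COPIES,
    fractions: tuple[float, ...] = MIXTURE_FRACTIONS,
    config: SimulationConfig = SimulationConfig(),
    n_replicates: int = 3,
) -> list[tuple[float, int, int, pd.DataFrame]]:
    """One plate per human fraction: (fraction, h_copies, m_copies, wells).

    ``h_copies = round(f * total)``; per-plate generators are spawned
    from the config seed so the series is reproducible as a whole.
    """
    if any(not 0 <= f <= 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    out = []
    for i, f in enumerate(fractions):
        h = round(f * total_copies)
        m = total_copies - h
        plate_cfg = replace(config, seed=_spawn_seed(config.seed, i))
        plate = simulate_plate(
            h, m, n_replicates, plate_cfg, sample_id=f"mix_h{f:g}"
        )
        out.append((f, h, m, plate))
    return out


def _spawn_seed(seed: int, index: int) -> int:
    child = np.random.SeedSequence(seed).spawn(index + 1)[index]
    return int(child.generate_state(1)[0])


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Per-base copy keeping each base with probability ``identity``.

    Mismatched positions receive a uniformly random *different* base, so
    ``identity`` is the exact expected sequence identity.
    """
    if identity >= 1.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    flip = rng.random(len(arr)) >= identity
    for i in np.nonzero(flip)[0]:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def _gff3_text(chrom: str, gene_id: str, exons: list[tuple[int, int]], strand: str = "+") -> str:
    """GFF3 (1-based inclusive) for one gene with one transcript."""
    tid = f"{gene_id}.t1"
    lines = ["##gff-version 3"]
    gene_start, gene_end = exons[0][0] + 1, exons[-1][1]
    lines.append(
        f"{chrom}\tintronq\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t"
        f"ID={gene_id};gene_id={gene_id}"
    )
    lines.append(
        f"{chrom}\tintronq\tmRNA\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t"
        f"ID={tid};Parent={gene_id};gene_id={gene_id}"
    )
    for start0, end0 in exons:
        lines.append(
            f"{chrom}\tintronq\texon\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t"
            f"Parent={tid};gene_id={gene_id}"
        )
    return "\n".join(lines) + "\n"


def synthetic_genome_pair(spec: SyntheticGenomeSpec = SyntheticGenomeSpec()) -> GenomePair:
    """Two genomes sharing a gene: conserved exons, divergent introns.

    Species A is drawn uniformly at random; species B copies A's exons
    at ``exon_identity`` and A's introns at ``intron_identity`` (0 =
    fully resampled, 1 = identical, which makes the species
    indistinguishable to any intronic assay). Deterministic in the seed.
    """
    rng = np.random.default_rng(spec.seed)
    flank_a = _random_dna(rng, spec.flank_length)
    flank_b = _random_dna(rng, spec.flank_length)
    exons_a = [_random_dna(rng, l) for l in spec.exon_lengths]
    introns_a = [_random_dna(rng, l) for l in spec.intron_lengths]
    exons_b = [_mutate(rng, e, spec.exon_identity) for e in exons_a]
    introns_b = [_mutate(rng, i, spec.intron_identity) for i in introns_a]
    tail_a = _random_dna(rng, spec.flank_length)
    tail_b = _random_dna(rng, spec.flank_length)

    def assemble(flank, exons, introns, tail):
        parts = [flank]
        coords = []
        pos = spec.flank_length
        for i, exon in enumerate(exons):
            parts.append(exon)
            coords.append((pos, pos + len(exon)))
            pos += len(exon)
            if i < len(introns):
                parts.append(introns[i])
                pos += len(introns[i])
        parts.append(tail)
        return "".join(parts), coords

    seq_a, coords_a = assemble(flank_a, exons_a, introns_a, tail_a)
    seq_b, coords_b = assemble(flank_b, exons_b, introns_b, tail_b)
    genome_a = GenomeSequence(id="speciesA_chr1", seq=seq_a)
    genome_b = GenomeSequence(id="speciesB_chr1", seq=seq_b)
    return GenomePair(
        genome_a=genome_a,
        genome_b=genome_b,
        gff_a=_gff3_text(genome_a.id, spec.gene_id, coords_a),
        gff_b=_gff3_text(genome_b.id, spec.gene_id, coords_b),
        gene_id=spec.gene_id,
        exon_starts=tuple(s for s, _ in coords_a),
    )
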