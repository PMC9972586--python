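"""Design and validation of species-discriminating intronic qPCR assays.

Both primers of an assay sit entirely inside the two introns flanking a
short exon, so the pair amplifies genomic DNA but can never amplify
spliced cDNA. On-target in-silico PCR requires perfect primer matches;
the cross-species check uses a relaxed annealing model (limited
mismatches outside a perfect 3'-terminal seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from itertools import groupby

from Bio.SeqUtils import MeltingTemp as mt
from Bio.SeqUtils import gc_fraction

from .genome_io import GeneModel, GenomeSequence, Interval, reverse_complement

__all__ = [
    "DesignParams",
    "PrimerPair",
    "Probe",
    "Amplicon",
    "SpecificityReport",
    "CandidateSite",
    "DesignResult",
    "melting_temperature",
    "enumerate_candidate_sites",
    "design_primer_pairs",
    "insilico_pcr",
    "cross_species_specificity",
    "verify_genomic_only",
    "place_probe",
]

#: Nearest-neighbor parameter set used throughout (SantaLucia 1998 unified
#: table as distributed with Biopython, DNA_NN3) with the salt correction
#: dS' = dS + 0.368 (N-1) ln[Na+]; recorded here for reproducibility.
TM_MODEL = "santalucia1998-unified/saltcorr-0.368*(N-1)*ln(Na)"

_NN_TABLE = mt.DNA_NN3
_SALTCORR = 5  # Biopython's id for the 0.368*(N-1)*ln[Na+] entropy correction


def melting_temperature(seq: str, salt_mM: float = 50.0, oligo_nM: float = 500.0) -> float:
    """Nearest-neighbor duplex melting temperature in deg C.

    Parameters follow qPCR convention: monovalent salt in mM, total
    oligo concentration in nM (template in excess not modelled). The
    sequence must be fully specified (no N) and at least 8 nt.
    """
    if len(seq) < 8:
        raise ValueError(f"sequence too short for NN model: {len(seq)} nt")
    if any(c not in "ACGT" for c in seq):
        raise ValueError(f"sequence contains non-ACGT characters: {seq!r}")
    return mt.Tm_NN(
        seq,
        nn_table=_NN_TABLE,
        Na=salt_mM,
        K=0,
        Tris=0,
        Mg=0,
        dNTPs=0,
        dnac1=oligo_nM,
        dnac2=0,
        selfcomp=False,
        saltcorr=_SALTCORR,
    )


@dataclass(frozen=True)
class DesignParams:
    """Filtering and ranking constraints for primer/probe design."""

    primer_len_min: int = 18
    primer_len_max: int = 25
    amplicon_len_min: int = 80
    amplicon_len_max: int = 300
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 40.0
    gc_max: float = 60.0
    max_homopolymer: int = 4
    max_exon_len: int = 150
    min_intron_len: int | None = None  # default: primer_len_max + 10
    salt_mM: float = 50.0
    oligo_nM: float = 500.0
    probe_len_min: int = 18
    probe_len_max: int = 30
    probe_tm_delta: float = 5.0

    def __post_init__(self) -> None:
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("empty primer length range")
        if self.amplicon_len_min > self.amplicon_len_max:
            raise ValueError("empty amplicon length range")
        if not self.tm_min <= self.tm_opt <= self.tm_max:
            raise ValueError("require tm_min <= tm_opt <= tm_max")
        if self.gc_min > self.gc_max:
            raise ValueError("empty GC range")

    @property
    def effective_min_intron_len(self) -> int:
        if self.min_intron_len is not None:
            return self.min_intron_len
        return self.primer_len_max + 10


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on the plus strand of a template."""

    interval: Interval
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.interval.length:
            raise ValueError("amplicon sequence/interval length mismatch")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class PrimerPair:
    """A convergent intronic primer pair with its thermodynamic summary."""

    forward_seq: str
    reverse_seq: str  # 5'->3' as synthesized (reverse complement of template)
    forward_interval: Interval
    reverse_interval: Interval
    species_tag: str
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    amplicon: Interval
    penalty: float

    @property
    def amplicon_len(self) -> int:
        return self.amplicon.length


@dataclass(frozen=True)
class Probe:
    """A hydrolysis probe placed strictly between the two primers."""

    seq: str
    interval: Interval
    tm: float
    reporter: str = "FAM"
    quencher: str = "TAMRA"


@dataclass(frozen=True)
class SpecificityReport:
    off_target_products: tuple[tuple[Interval, int], ...]
    notes: str = ""

    @property
    def verdict(self) -> str:
        return "pass" if not self.off_target_products else "fail"


@dataclass(frozen=True)
class CandidateSite:
    """A short exon together with its two flanking introns."""

    upstream_intron: Interval
    exon: Interval
    downstream_intron: Interval


@dataclass(frozen=True)
class DesignResult:
    pairs: tuple[PrimerPair, ...]
    rejections: dict[str, int] = field(default_factory=dict)


def enumerate_candidate_sites(
    gene_model: GeneModel, params: DesignParams = DesignParams()
) -> list[CandidateSite]:
    """All exons short enough to bridge, flanked by primer-capable introns."""
    sites = []
    min_intron = params.effective_min_intron_len
    for i in range(1, len(gene_model.exons) - 1):
        exon = gene_model.exons[i]
        up, down = gene_model.introns[i - 1], gene_model.introns[i]
        if exon.length > params.max_exon_len:
            continue
        if up.length < min_intron or down.length < min_intron:
            continue
        sites.append(CandidateSite(up, exon, down))
    return sites


def _max_homopolymer(seq: str) -> int:
    return max(len(list(g)) for _, g in groupby(seq))


def _candidate_windows(
    genome: GenomeSequence,
    intron: Interval,
    params: DesignParams,
    rejections: Counter,
) -> list[tuple[Interval, str, float, float]]:
    """Windows inside one intron passing the per-primer filters.

    Returns (interval, plus-strand seq, Tm, GC%) tuples; the caller
    derives the synthesized sequence per orientation.
    """
    out = []
    for start in range(intron.start, intron.end - params.primer_len_min + 1):
        for length in range(params.primer_len_min, params.primer_len_max + 1):
            end = start + length
            if end > intron.end:
                break
            seq = genome.seq[start:end]
            if "N" in seq:
                rejections["contains_N"] += 1
                continue
            if _max_homopolymer(seq) > params.max_homopolymer:
                rejections["homopolymer"] += 1
                continue
            gc = 100.0 * gc_fraction(seq)
            if not params.gc_min <= gc <= params.gc_max:
                rejections["gc"] += 1
                continue
            tm = melting_temperature(seq, params.salt_mM, params.oligo_nM)
            if not params.tm_min <= tm <= params.tm_max:
                rejections["tm"] += 1
                continue
            out.append((Interval(start, end), seq, tm, gc))
    return out


def design_primer_pairs(
    site: CandidateSite,
    genome: GenomeSequence,
    params: DesignParams = DesignParams(),
    top_k: int = 5,
    species_tag: str = "",
) -> DesignResult:
    """Exhaustive scan of primer windows in the two flanking introns.

    Forward primers are plus-strand windows of the upstream intron;
    reverse primers are reverse complements of downstream-intron
    windows, so every pair brackets (and the product contains) the
    enclosed exon. Ranking is by ascending penalty with positional
    tie-breaks, making the output independent of enumeration order.
    """
    rejections: Counter = Counter()
    # reverse-primer Tm/GC computed on the synthesized (revcomp) strand;
    # Tm and GC are strand-symmetric so plus-strand values are reused
    fwd = _candidate_windows(genome, site.upstream_intron, params, rejections)
    rev = _candidate_windows(genome, site.downstream_intron, params, rejections)
    mid_amp = (params.amplicon_len_min + params.amplicon_len_max) / 2.0
    pairs = []
    for f_iv, f_seq, f_tm, f_gc in fwd:
        for r_iv, r_plus_seq, r_tm, r_gc in rev:
            amp_len = r_iv.end - f_iv.start
            if not params.amplicon_len_min <= amp_len <= params.amplicon_len_max:
                rejections["amplicon_len"] += 1
                continue
            penalty = (
                abs(f_tm - params.tm_opt)
                + abs(r_tm - params.tm_opt)
                + abs(f_tm - r_tm)
                + abs(amp_len - mid_amp) / 100.0
                + abs(f_gc - 50.0) / 10.0
                + abs(r_gc - 50.0) / 10.0
            )
            pairs.append(
                PrimerPair(
                    forward_seq=f_seq,
                    reverse_seq=reverse_complement(r_plus_seq),
                    forward_interval=f_iv,
                    reverse_interval=r_iv,
                    species_tag=species_tag,
                    tm_f=f_tm,
                    tm_r=r_tm,
                    gc_f=f_gc,
                    gc_r=r_gc,
                    amplicon=Interval(f_iv.start, r_iv.end),
                    penalty=penalty,
                )
            )
    pairs.sort(
        key=lambda p: (p.penalty, p.forward_interval.start, p.reverse_interval.start)
    )
    return DesignResult(pairs=tuple(pairs[:top_k]), rejections=dict(rejections))


def _exact_sites(primer: str, template: str) -> tuple[list[int], list[int]]:
    """Plus-strand and minus-strand perfect binding positions of a primer."""
    plus, minus = [], []
    rc = reverse_complement(primer)
    pos = template.find(primer)
    while pos != -1:
        plus.append(pos)
        pos = template.find(primer, pos + 1)
    pos = template.find(rc)
    while pos != -1:
        minus.append(pos)
        pos = template.find(rc, pos + 1)
    return plus, minus


def _products_from_sites(
    plus_sites: list[tuple[int, int]],
    minus_sites: list[tuple[int, int]],
    template: str,
    max_product_len: int,
) -> list[Amplicon]:
    """Pair plus-strand and downstream minus-strand sites into products.

    Product spans the forward primer's 5' end through the reverse
    primer's 5' end inclusive.
    """
    products = []
    seen = set()
    for i, len_f in plus_sites:
        for j, len_r in minus_sites:
            if j < i:
                continue
            end = j + len_r
            if end < i + len_f:
                continue
            length = end - i
            if length > max_product_len:
                continue
            if (i, end) in seen:
                continue
            seen.add((i, end))
            products.append(
                Amplicon(interval=Interval(i, end), sequence=template[i:end])
            )
    products.sort(key=lambda a: (a.interval.start, a.interval.end))
    return products


def insilico_pcr(
    primer_pair: PrimerPair | tuple[str, str],
    template: GenomeSequence | str,
    max_product_len: int = 2000,
) -> list[Amplicon]:
    """Predict products from perfect-match primer binding sites.

    Considers every convergent combination of the two primers on both
    strands (including single-primer products), bounded by
    ``max_product_len``. Deterministic ordering by product position.
    """
    if isinstance(primer_pair, PrimerPair):
        f, r = primer_pair.forward_seq, primer_pair.reverse_seq
    else:
        f, r = primer_pair
    seq = template.seq if isinstance(template, GenomeSequence) else template
    plus: list[tuple[int, int]] = []
    minus: list[tuple[int, int]] = []
    for primer in dict.fromkeys((f, r)):  # dedupe if F == R
        p, m = _exact_sites(primer, seq)
        plus += [(pos, len(primer)) for pos in p]
        minus += [(pos, len(primer)) for pos in m]
    return _products_from_sites(plus, minus, seq, max_product_len)


def _relaxed_sites(
    primer: str, template: str, max_mismatches: int, seed_len: int
) -> tuple[list[int], list[int]]:
    """Binding positions tolerating mismatches outside a perfect 3' seed.

    A plus-strand site aligns the primer left-to-right (3' end at the
    window's right edge); a minus-strand site matches the primer's
    reverse complement (3' end at the window's left edge).
    """
    n, m = len(template), len(primer)
    seed = min(seed_len, m)
    plus, minus = [], []
    rc = reverse_complement(primer)
    for pos in range(n - m + 1):
        window = template[pos : pos + m]
        if window[m - seed :] == primer[m - seed :]:
            mm = sum(a != b for a, b in zip(window, primer))
            if mm <= max_mismatches:
                plus.append(pos)
        if window[:seed] == rc[:seed]:
            mm = sum(a != b for a, b in zip(window, rc))
            if mm <= max_mismatches:
                minus.append(pos)
    return plus, minus


def cross_species_specificity(
    primer_pair: PrimerPair | tuple[str, str],
    off_target_genome: GenomeSequence | str,
    max_product_len: int = 2000,
    allowed_mismatches: int = 2,
    seed_len: int = 12,
) -> SpecificityReport:
    """Scan the sibling genome under a relaxed annealing model.

    A binding site is accepted with up to ``allowed_mismatches`` total
    mismatches provided the 3'-terminal ``seed_len`` bases match
    perfectly. The assay passes iff no productive site pair exists.
    """
    if isinstance(primer_pair, PrimerPair):
        f, r = primer_pair.forward_seq, primer_pair.reverse_seq
    else:
        f, r = primer_pair
    seq = (
        off_target_genome.seq
        if isinstance(off_target_genome, GenomeSequence)
        else off_target_genome
    )
    plus: list[tuple[int, int]] = []
    minus: list[tuple[int, int]] = []
    for primer in dict.fromkeys((f, r)):
        p, m = _relaxed_sites(primer, seq, allowed_mismatches, seed_len)
        plus += [(pos, len(primer)) for pos in p]
        minus += [(pos, len(primer)) for pos in m]
    products = _products_from_sites(plus, minus, seq, max_product_len)
    hits = tuple((a.interval, a.length) for a in products)
    notes = (
        f"{len(hits)} off-target product(s) under <= {allowed_mismatches} "
        f"mismatches with perfect {seed_len} nt 3' seed"
        if hits
        else "no off-target products"
    )
    return SpecificityReport(off_target_products=hits, notes=notes)


def verify_genomic_only(
    primer_pair: PrimerPair, gene_model: GeneModel
) -> tuple[bool, str]:
    """Check that the assay can only amplify genomic DNA, never cDNA.

    True iff both primers are fully intronic (absent from any spliced
    transcript) and the amplicon brackets at least one complete exon.
    """
    for label, iv in (
        ("forward", primer_pair.forward_interval),
        ("reverse", primer_pair.reverse_interval),
    ):
        if not any(intron.contains(iv) for intron in gene_model.introns):
            for k, exon in enumerate(gene_model.exons, start=1):
                if exon.overlaps(iv):
                    return False, (
                        f"{label} primer overlaps exon {k} "
                        f"[{exon.start},{exon.end}); it would survive splicing"
                    )
            return False, f"{label} primer is not contained in any intron"
    spanned = [
        k
        for k, exon in enumerate(gene_model.exons, start=1)
        if primer_pair.amplicon.contains(exon)
    ]
    if not spanned:
        return False, "no exon spanned: both primers flank the same intron gap"
    return True, f"intronic primers; amplicon contains exon(s) {spanned}"


def place_probe(
    primer_pair: PrimerPair,
    template: GenomeSequence | str,
    params: DesignParams = DesignParams(),
) -> Probe | None:
    """Place a hydrolysis probe strictly between the two primers.

    Requires probe Tm at least ``probe_tm_delta`` deg C above the hotter
    primer and no 5'-terminal G (which would quench the reporter).
    Highest Tm wins, ties broken by leftmost position.
    """
    seq = template.seq if isinstance(template, GenomeSequence) else template
    lo = primer_pair.forward_interval.end
    hi = primer_pair.reverse_interval.start
    tm_floor = max(primer_pair.tm_f, primer_pair.tm_r) + params.probe_tm_delta
    best: Probe | None = None
    for start in range(lo, hi - params.probe_len_min + 1):
        for length in range(params.probe_len_min, params.probe_len_max + 1):
            end = start + length
            if end > hi:
                break
            window = seq[start:end]
            if "N" in window or window[0] == "G":
                continue
            if _max_homopolymer(window) > params.max_homopolymer:
                continue
            tm = melting_temperature(window, params.salt_mM, params.oligo_nM)
            if tm < tm_floor:
                continue
            if best is None or tm > best.tm:
                best = Probe(seq=window, interval=Interval(start, end), tm=tm)
    return best
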