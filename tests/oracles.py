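"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's code paths: the Tm oracle is a
hand summation over the SantaLucia (1998) unified nearest-neighbor
table, and the PCR oracle is a naive O(n*m) sliding-window scan.
"""

from __future__ import annotations

import math

# SantaLucia 1998 unified parameters: (dH kcal/mol, dS cal/mol/K)
_NN = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _step(dinuc: str) -> tuple[float, float]:
    return _NN.get(dinuc) or _NN[revcomp(dinuc)]


def tm_nearest_neighbor(seq: str, salt_mM: float = 50.0, oligo_nM: float = 500.0) -> float:
    """Hand-summed NN melting temperature (deg C).

    Tm = 1000*dH / (dS + R ln C) - 273.15 with the 0.368 (N-1) ln[Na+]
    entropic salt correction; C is the oligo concentration in mol/L
    (template assumed absent).
    """
    dh, ds = 0.0, 0.0
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT[terminal]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = _step(seq[i : i + 2])
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(salt_mM / 1000.0)
    conc = oligo_nM * 1e-9
    return 1000.0 * dh / (ds + 1.987 * math.log(conc)) - 273.15


def naive_insilico_pcr(
    primer_f: str, primer_r: str, template: str, max_product_len: int = 2000
) -> list[tuple[int, int]]:
    """All (start, end) products by exhaustive per-position comparison."""
    plus: list[tuple[int, int]] = []
    minus: list[tuple[int, int]] = []
    for primer in {primer_f, primer_r}:
        m = len(primer)
        rc = revcomp(primer)
        for pos in range(len(template) - m + 1):
            window = template[pos : pos + m]
            if window == primer:
                plus.append((pos, m))
            if window == rc:
                minus.append((pos, m))
    products = set()
    for i, len_f in plus:
        for j, len_r in minus:
            if j < i:
                continue
            end = j + len_r
            if end < i + len_f or end - i > max_product_len:
                continue
            products.add((i, end))
    return sorted(products)
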