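"""Ct-based quantification: composition, copy numbers, sensitivity, growth.

Conventions
-----------
* A well whose fluorescence never crosses threshold is *censored*; its
  Ct is recorded at the final cycle (default 40) when aggregating, and a
  detection floor is reported alongside because the true Ct may be higher.
* Amplification is assumed exactly twofold per cycle, so a Ct difference
  of d cycles maps to a 2**d fold ratio of starting copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "QpcrWell",
    "CtSummary",
    "CompositionEstimate",
    "QuantConstants",
    "GrowthRecord",
    "aggregate_replicates",
    "fold_from_delta_ct",
    "composition_from_ct",
    "sensitivity_from_delta_ct",
    "mass_to_copies",
    "copies_to_mass",
    "relative_quantification",
    "doubling_time",
    "tumor_volume",
    "read_ct_table",
    "quantify_table",
    "write_composition_report",
    "REPORT_COLUMNS",
]

#: String tokens in a Ct column that denote a censored (undetermined) well.
CENSORED_TOKENS = {"undetermined", "n/a", "na", ""}

HUMAN_ASSAY_ALIASES = {"human", "h", "hgapdh"}
MOUSE_ASSAY_ALIASES = {"mouse", "murine", "m", "mgapdh"}

REPORT_COLUMNS = [
    "sample_id",
    "n",
    "hCt_mean",
    "hCt_sem",
    "mCt_mean",
    "mCt_sem",
    "delta_ct",
    "fold",
    "human_pct",
    "murine_pct",
    "detection_flag",
    "detection_floor_pct",
]


@dataclass(frozen=True)
class QuantConstants:
    """Physical constants and conventions used in copy-number conversion."""

    avogadro: float = 6.022e23  # 1/mol
    bp_mass: float = 650.0  # g/mol per base pair
    human_genome_len: float = 3.2e9  # nt
    mouse_genome_len: float = 2.5e9  # nt
    censor_cycle: float = 40.0

    def __post_init__(self) -> None:
        for name in ("avogadro", "bp_mass", "human_genome_len", "mouse_genome_len", "censor_cycle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class QpcrWell:
    """One well: a Ct reading (None when censored) for one sample/assay."""

    sample_id: str
    assay: str
    ct: float | None
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.ct is not None and not self.ct > 0:
            raise ValueError(f"ct must be positive, got {self.ct}")


@dataclass(frozen=True)
class CtSummary:
    mean_ct: float
    sem: float
    n: int
    n_censored: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if not 0 <= self.n_censored <= self.n:
            raise ValueError("n_censored out of range")

    @property
    def fully_censored(self) -> bool:
        return self.n_censored == self.n


@dataclass(frozen=True)
class CompositionEstimate:
    delta_ct: float  # hCt - mCt
    fold: float  # 2**|delta_ct|, in favor of the lower-Ct species
    human_pct: float
    murine_pct: float
    dominant: str  # human | mouse | balanced
    detection_flag: str = "none"  # none | human_not_detected | mouse_not_detected
    detection_floor_pct: float | None = None


@dataclass(frozen=True)
class GrowthRecord:
    T: float  # elapsed time, hours
    Xb: float  # starting cell count
    Xe: float  # ending cell count

    def __post_init__(self) -> None:
        if self.T <= 0 or self.Xb <= 0 or self.Xe <= 0:
            raise ValueError("T, Xb and Xe must all be positive")


def aggregate_replicates(
    cts: Iterable[float | None], censor_cycle: float = 40.0
) -> CtSummary:
    """Mean +- SEM over replicate Cts, censored wells entered at the cap.

    SEM uses the sample standard deviation (ddof=1) over sqrt(n); a
    single replicate reports SEM 0.
    """
    values = []
    n_censored = 0
    for ct in cts:
        if ct is None or (isinstance(ct, float) and math.isnan(ct)):
            values.append(censor_cycle)
            n_censored += 1
        else:
            values.append(float(ct))
    if not values:
        raise ValueError("no replicate wells to aggregate")
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        sem = 0.0
    else:
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        sem = math.sqrt(var) / math.sqrt(n)
    return CtSummary(mean_ct=mean, sem=sem, n=n, n_censored=n_censored)


def fold_from_delta_ct(delta_ct: float) -> float:
    """Fold ratio 2**|dCt| in favor of the lower-Ct assay."""
    if not math.isfinite(delta_ct):
        raise ValueError("delta_ct must be finite")
    return 2.0 ** abs(delta_ct)


def sensitivity_from_delta_ct(delta_ct: float) -> float:
    """Detection sensitivity (percent) from a non-negative Ct separation.

    100-fold separation (dCt 6.64386) -> 1%; 1,000-fold -> 0.1%;
    10,000-fold -> 0.01%.
    """
    if delta_ct < 0:
        raise ValueError("delta_ct must be >= 0 (resolve orientation first)")
    return 100.0 / 2.0**delta_ct


def composition_from_ct(
    h_summary: CtSummary,
    m_summary: CtSummary,
    censor_cycle: float = 40.0,
) -> CompositionEstimate:
    """Human/murine composition from the two assays' mean Cts.

    With F = 2**(mCt - hCt): human% = F/(F+1)*100 and murine% is its
    exact complement. When one assay is fully censored, its wells enter
    at the censor cycle (point estimate) and a detection floor — the
    largest fraction the undetected species could hold — is attached.
    """
    if h_summary.fully_censored and m_summary.fully_censored:
        raise ValueError("no template detected: both assays fully censored")
    h_ct, m_ct = h_summary.mean_ct, m_summary.mean_ct
    delta = h_ct - m_ct
    f = 2.0 ** (m_ct - h_ct)
    human_pct = f / (f + 1.0) * 100.0
    murine_pct = 100.0 - human_pct
    if delta < 0:
        dominant = "human"
    elif delta > 0:
        dominant = "mouse"
    else:
        dominant = "balanced"
    flag, floor = "none", None
    if h_summary.fully_censored:
        flag = "human_not_detected"
        floor = 100.0 / 2.0 ** (censor_cycle - m_ct)
    elif m_summary.fully_censored:
        flag = "mouse_not_detected"
        floor = 100.0 / 2.0 ** (censor_cycle - h_ct)
    return CompositionEstimate(
        delta_ct=delta,
        fold=fold_from_delta_ct(delta),
        human_pct=human_pct,
        murine_pct=murine_pct,
        dominant=dominant,
        detection_flag=flag,
        detection_floor_pct=floor,
    )


def mass_to_copies(
    amount_ng: float,
    genome_len_nt: float,
    constants: QuantConstants = QuantConstants(),
) -> float:
    """Genome copies in ``amount_ng`` of DNA of a given genome length.

    copies = amount_ng * N_A / (genome_len * 1e9 * 650); the 1e9 factor
    converts ng to g.
    """
    if genome_len_nt <= 0:
        raise ValueError("genome length must be positive")
    if amount_ng < 0:
        raise ValueError("amount must be >= 0")
    return amount_ng * constants.avogadro / (genome_len_nt * 1e9 * constants.bp_mass)


def copies_to_mass(
    copies: float,
    genome_len_nt: float,
    constants: QuantConstants = QuantConstants(),
) -> float:
    """Exact algebraic inverse of :func:`mass_to_copies` (result in ng)."""
    if genome_len_nt <= 0:
        raise ValueError("genome length must be positive")
    if copies < 0:
        raise ValueError("copies must be >= 0")
    return copies * genome_len_nt * 1e9 * constants.bp_mass / constants.avogadro


def relative_quantification(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """RQ = 2**(-ddCt) relative expression."""
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return 2.0**-ddct


def doubling_time(record: GrowthRecord) -> float:
    """dt = T * ln2 / ln(Xe/Xb); requires net growth."""
    if record.Xe <= record.Xb:
        raise ValueError("no net growth: Xe must exceed Xb")
    return record.T * math.log(2.0) / math.log(record.Xe / record.Xb)


def tumor_volume(width_mm: float, length_mm: float) -> float:
    """TV = width**2 * length / 2 (mm^3)."""
    if width_mm < 0 or length_mm < 0:
        raise ValueError("width and length must be >= 0")
    return width_mm**2 * length_mm / 2.0


def _parse_ct(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        if value.strip().lower() in CENSORED_TOKENS:
            return None
        return float(value)
    return float(value)


def _normalize_assay(label: str) -> str:
    key = str(label).strip().lower()
    if key in HUMAN_ASSAY_ALIASES:
        return "human"
    if key in MOUSE_ASSAY_ALIASES:
        return "mouse"
    raise ValueError(
        f"unknown assay label {label!r}; expected one of "
        f"{sorted(HUMAN_ASSAY_ALIASES | MOUSE_ASSAY_ALIASES)}"
    )


def read_ct_table(path: str | Path) -> list[QpcrWell]:
    """Read a CSV/TSV Ct table (columns sample_id, assay, replicate, ct).

    Ct values "Undetermined", "N/A" or empty parse as censored.
    Delimiter is sniffed, so both CSV and TSV exports work.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"sample_id", "assay", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("Ct table contains no wells")
    wells = []
    for row in df.itertuples(index=False):
        wells.append(
            QpcrWell(
                sample_id=str(row.sample_id),
                assay=_normalize_assay(row.assay),
                ct=_parse_ct(row.ct),
                replicate=int(row.replicate),
            )
        )
    return wells


def quantify_table(
    wells: Sequence[QpcrWell],
    censor_cycle: float = 40.0,
) -> pd.DataFrame:
    """Per-sample composition report over a table of wells.

    One row per sample, ordered by sample_id. A sample missing one
    assay entirely is reported with the matching detection flag (its
    absent assay treated as fully censored at the cap).
    """
    if not wells:
        raise ValueError("no wells provided")
    by_sample: dict[str, dict[str, list[QpcrWell]]] = {}
    for w in wells:
        by_sample.setdefault(w.sample_id, {}).setdefault(w.assay, []).append(w)
    rows = []
    for sample_id in sorted(by_sample):
        assays = by_sample[sample_id]
        summaries = {}
        for assay in ("human", "mouse"):
            group = sorted(assays.get(assay, []), key=lambda w: w.replicate)
            if group:
                summaries[assay] = aggregate_replicates(
                    [w.ct for w in group], censor_cycle
                )
            else:
                sibling = assays.get("mouse" if assay == "human" else "human", [])
                n = max(len(sibling), 1)
                summaries[assay] = CtSummary(
                    mean_ct=censor_cycle, sem=0.0, n=n, n_censored=n
                )
        h, m = summaries["human"], summaries["mouse"]
        est = composition_from_ct(h, m, censor_cycle)
        rows.append(
            {
                "sample_id": sample_id,
                "n": max(h.n, m.n),
                "hCt_mean": h.mean_ct,
                "hCt_sem": h.sem,
                "mCt_mean": m.mean_ct,
                "mCt_sem": m.sem,
                "delta_ct": est.delta_ct,
                "fold": est.fold,
                "human_pct": est.human_pct,
                "murine_pct": est.murine_pct,
                "detection_flag": est.detection_flag,
                "detection_floor_pct": est.detection_floor_pct,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_composition_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write the composition report as TSV, percentages to 4 decimals."""
    out = df.copy()
    for col in ("human_pct", "murine_pct"):
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    out["detection_floor_pct"] = out["detection_floor_pct"].map(
        lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.6g}"
    )
    for col in ("hCt_mean", "hCt_sem", "mCt_mean", "mCt_sem", "delta_ct"):
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    out["fold"] = out["fold"].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)
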