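"""Cytotoxicity and genotoxicity index calculus.

Implements the scoring arithmetic of the cytokinesis-block micronucleus
(CBMN) assay — Replication Index, Cytokinesis-Block Proliferation Index,
micronucleus frequency — and the comet-assay damage moments (Tail Moment
and Olive Tail Moment) computed from per-cell measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

__all__ = [
    "MNScoreRecord",
    "CometCellRecord",
    "aggregate_mn",
    "replication_index",
    "cbpi",
    "mn_frequency",
    "tail_moment",
    "olive_tail_moment",
]

#: Regulatory scoring convention caps micronuclei counted per binucleated
#: cell; used as a sanity ceiling on n_mn.
MN_PER_CELL_CEILING = 6


@dataclass(frozen=True)
class MNScoreRecord:
    """Per-slide CBMN scoring counts.

    ``n_mono`` .. ``n_tetra`` are the numbers of cells with one to four
    nuclei among the ``n_total`` cells scored for nucleation status;
    ``n_mn`` micronuclei were found in ``n_bn_scored`` binucleated cells
    inspected for micronuclei (the MN scoring set may span slides, so
    ``n_bn_scored`` need not be bounded by ``n_bi``).
    """

    slide_id: str
    cell_line: str
    condition: str
    time_h: float
    n_mono: int
    n_bi: int
    n_tri: int
    n_tetra: int
    n_total: int
    n_bn_scored: int
    n_mn: int

    def __post_init__(self) -> None:
        counts = (
            self.n_mono, self.n_bi, self.n_tri, self.n_tetra,
            self.n_total, self.n_bn_scored, self.n_mn,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"negative count in record {self.slide_id!r}")
        if self.n_mono + self.n_bi + self.n_tri + self.n_tetra > self.n_total:
            raise ValueError(
                f"record {self.slide_id!r}: nucleation-class counts exceed n_total"
            )
        if self.n_mn > self.n_bn_scored * MN_PER_CELL_CEILING:
            raise ValueError(
                f"record {self.slide_id!r}: n_mn above the scoring ceiling of "
                f"{MN_PER_CELL_CEILING} per binucleated cell"
            )

    @property
    def n_multi(self) -> int:
        """Multinucleated cells (three or four nuclei)."""
        return self.n_tri + self.n_tetra

    @property
    def proliferation_fraction(self) -> float:
        """(binucleate + 2 x multinucleate) / total — the RI numerator."""
        if self.n_total == 0:
            raise ValueError("no cells scored")
        return (self.n_bi + 2 * self.n_multi) / self.n_total


@dataclass(frozen=True)
class CometCellRecord:
    """Single-cell comet measurements from image analysis.

    ``tail_dna_pct`` is the percentage of the comet's DNA fluorescence in
    the tail; ``tail_length`` and ``centroid_distance`` (head-to-tail
    intensity-centroid distance) share one length unit per dataset.
    """

    cell_id: str
    cell_line: str
    condition: str
    time_h: float
    tail_dna_pct: float
    tail_length: float
    centroid_distance: float
    slide_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.tail_dna_pct <= 100.0:
            raise ValueError(
                f"cell {self.cell_id!r}: tail_dna_pct {self.tail_dna_pct} "
                "outside [0, 100]"
            )
        if self.tail_length < 0:
            raise ValueError(f"cell {self.cell_id!r}: negative tail_length")
        if self.centroid_distance < 0:
            raise ValueError(f"cell {self.cell_id!r}: negative centroid_distance")


def aggregate_mn(records: Iterable[MNScoreRecord]) -> MNScoreRecord:
    """Pool per-slide CBMN counts into one aggregated record.

    All records must share cell line, condition and time point.
    """
    recs = list(records)
    if not recs:
        raise ValueError("no records to aggregate")
    keys = {(r.cell_line, r.condition, r.time_h) for r in recs}
    if len(keys) > 1:
        raise ValueError(f"cannot pool across groups: {sorted(keys)}")
    first = recs[0]
    return replace(
        first,
        slide_id="+".join(r.slide_id for r in recs),
        n_mono=sum(r.n_mono for r in recs),
        n_bi=sum(r.n_bi for r in recs),
        n_tri=sum(r.n_tri for r in recs),
        n_tetra=sum(r.n_tetra for r in recs),
        n_total=sum(r.n_total for r in recs),
        n_bn_scored=sum(r.n_bn_scored for r in recs),
        n_mn=sum(r.n_mn for r in recs),
    )


def replication_index(treated: MNScoreRecord, control: MNScoreRecord) -> float:
    """Replication Index (RI), in percent.

    RI = [(bi + 2 x multi) / total]_treated / [same]_control x 100, where
    multinucleate pools the tri- and tetranucleated classes.  100 means
    treated and control cultures proliferated identically; values below
    100 quantify cytostasis.
    """
    if treated.n_total == 0 or control.n_total == 0:
        raise ValueError("RI undefined: zero cells scored")
    denom = control.proliferation_fraction
    if denom == 0:
        raise ValueError(
            "RI undefined: control culture shows no proliferating cells"
        )
    return treated.proliferation_fraction / denom * 100.0


def cbpi(record: MNScoreRecord) -> float:
    """Cytokinesis-Block Proliferation Index.

    CBPI = (1*N1 + 2*N2 + 3*(N3 + N4)) / N over the nucleation-scored
    cells: the average number of cell cycles per cell, bounded in [1, 3].
    """
    n = record.n_mono + record.n_bi + record.n_tri + record.n_tetra
    if n == 0:
        raise ValueError("CBPI undefined: zero cells scored")
    return (record.n_mono + 2 * record.n_bi + 3 * record.n_multi) / n


def mn_frequency(record: MNScoreRecord) -> float:
    """Micronuclei per 1000 binucleated cells."""
    if record.n_bn_scored == 0:
        raise ValueError("MN frequency undefined: zero binucleated cells scored")
    return record.n_mn / record.n_bn_scored * 1000.0


def tail_moment(cell: CometCellRecord) -> float:
    """Tail Moment: percent tail DNA times tail length, divided by 100."""
    return cell.tail_dna_pct * cell.tail_length / 100.0


def olive_tail_moment(cell: CometCellRecord) -> float:
    """Olive Tail Moment: percent tail DNA times the head-to-tail
    intensity-centroid distance, divided by 100."""
    return cell.tail_dna_pct * cell.centroid_distance / 100.0
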