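"""Alternative-splicing event classification from exon structures.

A query isoform is compared against a reference isoform of the same gene
and strand, and every structural difference is labeled with one of seven
event types: alternative transcription start/termination site (ATSS/ATTS),
intron retention (IR), mutually exclusive exons (MEE), exon skipping (ES),
and alternative 5' donor / 3' acceptor site choice (A5/A3). Coordinates are
1-based inclusive (GTF convention); donor/acceptor labels are strand-aware.
When several patterns could explain the same exons the precedence is
ATSS/ATTS, then IR, then MEE, then ES, then A5/A3: an isoform exon that
retains an intron is not additionally called A5/A3, and a skipped reference
exon that partners a mutually exclusive query exon is called MEE, not ES.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .coexpression import bh_adjust

EVENT_TYPES = ("A3", "A5", "ES", "MEE", "ATSS", "ATTS", "IR")


@dataclass(frozen=True)
class IsoformAnnotation:
    """Exon structure of one transcript isoform."""

    isoform_id: str
    gene_id: str
    strand: str
    exons: tuple[tuple[str, int, int], ...]  # (chrom, start, end), 1-based inclusive

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"isoform {self.isoform_id} has no exons")
        exs = tuple(sorted(self.exons, key=lambda e: (e[0], e[1])))
        prev_end = None
        for chrom, s, e in exs:
            if s > e:
                raise ValueError(f"exon start {s} > end {e} in {self.isoform_id}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"overlapping exons in {self.isoform_id}")
            prev_end = e
        object.__setattr__(self, "exons", exs)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][1], self.exons[-1][2]

    def tss(self) -> int:
        """Transcription start coordinate (strand-aware)."""
        return self.exons[0][1] if self.strand == "+" else self.exons[-1][2]

    def tts(self) -> int:
        """Transcription termination coordinate (strand-aware)."""
        return self.exons[-1][2] if self.strand == "+" else self.exons[0][1]


@dataclass(frozen=True)
class ASEvent:
    isoform_id: str
    event_type: str
    reference_isoform_id: str

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def classify_as_events(iso: IsoformAnnotation, ref: IsoformAnnotation) -> set[ASEvent]:
    """Classify all splicing differences of ``iso`` relative to ``ref``."""
    if iso.gene_id != ref.gene_id:
        raise ValueError(
            f"gene mismatch: {iso.isoform_id} ({iso.gene_id}) vs "
            f"{ref.isoform_id} ({ref.gene_id})"
        )
    if iso.strand != ref.strand:
        raise ValueError(f"strand mismatch between {iso.isoform_id} and {ref.isoform_id}")
    chroms = {c for c, _, _ in iso.exons} | {c for c, _, _ in ref.exons}
    if len(chroms) > 1:
        raise ValueError("isoforms span multiple chromosomes")

    I = [(s, e) for _, s, e in iso.exons]
    R = [(s, e) for _, s, e in ref.exons]
    events: set[str] = set()

    if iso.tss() != ref.tss():
        events.add("ATSS")
    if iso.tts() != ref.tts():
        events.add("ATTS")

    # Intron retention: a query exon fully spans two adjacent reference exons
    # plus the intervening intron. Such exons are excluded from A5/A3 calls.
    ir_iso_exons: set[int] = set()
    for xi, (s, e) in enumerate(I):
        for ri in range(len(R) - 1):
            s1, _ = R[ri]
            _, e2 = R[ri + 1]
            if s <= s1 and e >= e2:
                events.add("IR")
                ir_iso_exons.add(xi)

    def _novel_internal(query: list[tuple[int, int]], other: list[tuple[int, int]]) -> list[int]:
        """Indices of internal query exons overlapping no exon of ``other``."""
        out = []
        for qi in range(1, len(query) - 1):
            if not any(_overlaps(query[qi], oe) for oe in other):
                out.append(qi)
        return out

    def _containing_intron(exon: tuple[int, int], exons: list[tuple[int, int]]) -> tuple[int, int] | None:
        for k in range(len(exons) - 1):
            intron = (exons[k][1] + 1, exons[k + 1][0] - 1)
            if intron[0] <= exon[0] and exon[1] <= intron[1]:
                return intron
        return None

    novel_iso = _novel_internal(I, R)  # candidate mutually exclusive query exons
    novel_ref = _novel_internal(R, I)  # candidate skipped / exclusive ref exons
    mee_ref: set[int] = set()
    for xi in novel_iso:
        ref_intron = _containing_intron(I[xi], R)
        if ref_intron is None:
            continue
        for yi in novel_ref:
            if _overlaps(I[xi], R[yi]):
                continue
            iso_intron = _containing_intron(R[yi], I)
            if iso_intron is None:
                continue
            if _overlaps(ref_intron, iso_intron):
                events.add("MEE")
                mee_ref.add(yi)

    # Exon skipping: internal reference exon absent from the query within the
    # query's span, unless already explained as the MEE partner.
    span = (I[0][0], I[-1][1])
    for yi in novel_ref:
        if yi in mee_ref:
            continue
        if span[0] <= R[yi][0] and R[yi][1] <= span[1]:
            events.add("ES")

    # Alternative donor/acceptor: boundary differences of overlapping exon
    # pairs. A transcript-terminal boundary belongs to ATSS/ATTS, never A5/A3:
    # genomically, the leftmost exon's left edge and the rightmost exon's
    # right edge are transcript termini on either strand.
    left_label = "A3" if iso.strand == "+" else "A5"
    right_label = "A5" if iso.strand == "+" else "A3"
    for xi, x in enumerate(I):
        if xi in ir_iso_exons:
            continue
        for yi, y in enumerate(R):
            if not _overlaps(x, y):
                continue
            if x[0] != y[0] and xi != 0 and yi != 0:
                events.add(left_label)
            if x[1] != y[1] and xi != len(I) - 1 and yi != len(R) - 1:
                events.add(right_label)

    return {ASEvent(iso.isoform_id, ev, ref.isoform_id) for ev in events}


def choose_reference_isoforms(
    annotations: Mapping[str, IsoformAnnotation],
    if_matrix: pd.DataFrame,
    condition: pd.Series,
) -> dict[str, str]:
    """Per gene, pick the isoform with the highest mean IF in normal samples."""
    condition = condition.reindex(if_matrix.columns)
    normal_if = if_matrix.loc[:, (condition == "normal").to_numpy()].mean(axis=1)
    best: dict[str, tuple[float, str]] = {}
    for iso_id, ann in annotations.items():
        score = float(normal_if.get(iso_id, np.nan))
        if np.isnan(score):
            score = -np.inf
        cur = best.get(ann.gene_id)
        # deterministic: higher mean IF wins, ties break by isoform id
        key = (score, iso_id)
        if cur is None or (key[0] > cur[0]) or (key[0] == cur[0] and key[1] < cur[1]):
            best[ann.gene_id] = key
    return {gene: iso_id for gene, (_, iso_id) in best.items()}


def classify_switch_events(
    switch_isoforms: Iterable[str],
    annotations: Mapping[str, IsoformAnnotation],
    reference_of_gene: Mapping[str, str],
) -> set[ASEvent]:
    """Classify each switched isoform against its gene's reference isoform."""
    out: set[ASEvent] = set()
    for iso_id in switch_isoforms:
        ann = annotations.get(iso_id)
        if ann is None:
            continue
        ref_id = reference_of_gene.get(ann.gene_id)
        if ref_id is None or ref_id == iso_id:
            continue
        out |= classify_as_events(ann, annotations[ref_id])
    return out


def as_type_enrichment(events: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Fisher-exact gain/loss enrichment per AS event type.

    ``events`` needs columns ``event_type`` and ``direction`` (gain/loss),
    one row per classified event. For each type t the 2x2 table
    [[gain_t, loss_t], [gain_other, loss_other]] is tested two-sided and
    BH-corrected across testable types; a type with zero events is reported
    untestable.
    """
    bad_dir = set(events["direction"].unique()) - {"gain", "loss"}
    if bad_dir:
        raise ValueError(f"direction must be gain or loss, got {sorted(bad_dir)}")
    total_gain = int((events["direction"] == "gain").sum())
    total_loss = int((events["direction"] == "loss").sum())
    rows = []
    for etype in EVENT_TYPES:
        sub = events.loc[events["event_type"] == etype]
        g = int((sub["direction"] == "gain").sum())
        l = int((sub["direction"] == "loss").sum())
        testable = (g + l) > 0
        if testable:
            table = [[g, l], [total_gain - g, total_loss - l]]
            odds, p = st.fisher_exact(table, alternative="two-sided")
        else:
            odds, p = np.nan, np.nan
        rows.append((etype, g, l, odds, p, testable))
    out = pd.DataFrame(
        rows, columns=["event_type", "n_gain", "n_loss", "odds_ratio", "p_value", "testable"]
    )
    out["q_value"] = np.nan
    mask = out["testable"].to_numpy()
    if mask.any():
        out.loc[mask, "q_value"] = bh_adjust(out.loc[mask, "p_value"].to_numpy())
    out["significant"] = (out["q_value"] < q_threshold).fillna(False)
    return out


def read_gtf_annotations(path: str | Path) -> dict[str, IsoformAnnotation]:
    """Load exon structures per transcript from a GTF file."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    exons = df.loc[df["Feature"] == "exon"]
    out: dict[str, IsoformAnnotation] = {}
    for tid, grp in exons.groupby("transcript_id", sort=False):
        strands = grp["Strand"].unique()
        genes = grp["gene_id"].unique()
        if len(strands) != 1 or len(genes) != 1:
            raise ValueError(f"inconsistent strand/gene for transcript {tid}")
        # pyranges uses 0-based half-open starts; convert back to 1-based inclusive
        ex = tuple(
            (str(r.Chromosome), int(r.Start) + 1, int(r.End))
            for r in grp.itertuples()
        )
        out[str(tid)] = IsoformAnnotation(
            isoform_id=str(tid), gene_id=str(genes[0]), strand=str(strands[0]), exons=ex
        )
    return out


def write_gtf(annotations: Iterable[IsoformAnnotation], path: str | Path) -> None:
    """Write transcript/exon GTF lines for the given isoform structures."""
    with Path(path).open("w") as fh:
        for ann in annotations:
            chrom = ann.exons[0][0]
            s, e = ann.span
            attrs = f'gene_id "{ann.gene_id}"; transcript_id "{ann.isoform_id}";'
            fh.write(
                f"{chrom}\tsplicewalk\ttranscript\t{s}\t{e}\t.\t{ann.strand}\t.\t{attrs}\n"
            )
            for chrom_e, es, ee in ann.exons:
                fh.write(
                    f"{chrom_e}\tsplicewalk\texon\t{es}\t{ee}\t.\t{ann.strand}\t.\t{attrs}\n"
                )


def write_events(events: Iterable[ASEvent], path: str | Path) -> None:
    rows = sorted(
        (ev.isoform_id, ev.event_type, ev.reference_isoform_id) for ev in events
    )
    pd.DataFrame(rows, columns=["isoform_id", "event_type", "reference_isoform_id"]).to_csv(
        path, sep="\t", index=False
    )
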