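"""Scoring sBN edge directions against early/late colonizer labels.

Given literature-derived labels assigning taxa to early or late
colonizers, the report counts how many network edges connect labeled
taxa, how many directed edges run early -> late versus the inconsistent
late -> early, and the resulting direction-consistency percentage
``100 * (labeled - late_to_early) / labeled``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import pandas as pd

from .sbn import SignedBayesNet

EARLY, LATE = "early", "late"


@dataclass
class ColonizationLabels:
    """Map taxon -> 'early' | 'late'; unlisted taxa are unknown."""

    labels: dict

    def __post_init__(self) -> None:
        for taxon, lab in self.labels.items():
            if lab not in (EARLY, LATE):
                raise ValueError(
                    f"label for {taxon!r} must be 'early' or 'late', got {lab!r}"
                )

    def __getitem__(self, taxon: str):
        return self.labels.get(taxon)

    @classmethod
    def read_tsv(cls, path) -> "ColonizationLabels":
        """Two-column TSV: taxon <tab> early|late (no header)."""
        labels: dict = {}
        with open(path, newline="") as fh:
            for ln, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) != 2:
                    raise ValueError(f"line {ln}: expected 2 columns, got {len(row)}")
                taxon, lab = row[0].strip(), row[1].strip().lower()
                if taxon in labels and labels[taxon] != lab:
                    raise ValueError(f"taxon {taxon!r} labeled both "
                                     f"{labels[taxon]!r} and {lab!r}")
                labels[taxon] = lab
        return cls(labels)


@dataclass
class ConsistencyReport:
    """Per-network counts mirroring the columns of the oral-site summary
    table: total edges, directed edges, negatively correlated (red)
    edges, early->late arrows, labeled edges with an early endpoint,
    inconsistent late->early arrows, and the derived percentages."""

    total_edges: int = 0
    directed_edges: int = 0
    red_edges: int = 0
    early_to_late: int = 0
    early_related: int = 0
    late_to_early: int = 0
    labeled_edges: int = 0
    red_early_to_late: int = 0

    def __post_init__(self) -> None:
        if self.late_to_early > self.labeled_edges:
            raise ValueError("late_to_early exceeds labeled_edges")
        if self.directed_edges > self.total_edges:
            raise ValueError("directed_edges exceeds total_edges")

    @property
    def consistency_pct(self) -> float | None:
        if self.labeled_edges == 0:
            return None
        return round(
            100.0 * (self.labeled_edges - self.late_to_early)
            / self.labeled_edges, 1
        )

    @property
    def red_EL_pct(self) -> float | None:
        if self.early_to_late == 0:
            return None
        return round(100.0 * self.red_early_to_late / self.early_to_late, 1)


def consistency_report(net: SignedBayesNet,
                       labels: ColonizationLabels) -> ConsistencyReport:
    """Count labeled-edge orientations in ``net``.

    An edge is labeled when both endpoints carry a label. Undirected
    labeled edges count toward ``labeled_edges`` (and ``early_related``
    when an endpoint is early) but toward neither directional bucket.
    ``early_related`` is direction-agnostic: every labeled edge touching
    an early colonizer, including inconsistent late -> early arrows.
    """
    rep = ConsistencyReport()
    rep.total_edges = len(net.edges)
    rep.directed_edges = sum(e.directed for e in net.edges)
    rep.red_edges = sum(e.sign == "negative" for e in net.edges)
    for e in net.edges:
        src, tgt = labels[e.source], labels[e.target]
        if src is None or tgt is None:
            continue
        rep.labeled_edges += 1
        if EARLY in (src, tgt):
            rep.early_related += 1
        if e.directed and src == EARLY and tgt == LATE:
            rep.early_to_late += 1
            if e.sign == "negative":
                rep.red_early_to_late += 1
        elif e.directed and src == LATE and tgt == EARLY:
            rep.late_to_early += 1
    return rep


def _fmt_pct(x: float | None) -> str:
    return "NA" if x is None else f"{x:.1f}%"


def report_table(reports: list) -> pd.DataFrame:
    """Tabulate (site, report) pairs in the summary-table column layout."""
    rows = []
    for site, r in reports:
        rows.append({
            "site": site,
            "total": r.total_edges,
            "directed": r.directed_edges,
            "red": r.red_edges,
            "early_to_late": r.early_to_late,
            "early_related": r.early_related,
            "late_to_early": r.late_to_early,
            "labeled": r.labeled_edges,
            "consistency_pct": _fmt_pct(r.consistency_pct),
            "red_EL_pct": _fmt_pct(r.red_EL_pct),
        })
    return pd.DataFrame(rows)


def aggregate_reports(reports: list, path=None):
    """Column-wise sums over (site, report) pairs, with percentages
    recomputed from the summed counts (never averaged across sites).

    Returns ``(aggregate, table)``; the table carries one row per site
    plus a ``Total`` row and is written as TSV when ``path`` is given.
    """
    agg = ConsistencyReport()
    for _, r in reports:
        agg.total_edges += r.total_edges
        agg.directed_edges += r.directed_edges
        agg.red_edges += r.red_edges
        agg.early_to_late += r.early_to_late
        agg.early_related += r.early_related
        agg.late_to_early += r.late_to_early
        agg.labeled_edges += r.labeled_edges
        agg.red_early_to_late += r.red_early_to_late
    table = report_table(list(reports) + [("Total", agg)])
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return agg, table
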