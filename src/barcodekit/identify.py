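"""Specimen-identification criteria for barcode reference libraries.

Three distance-based criteria ("best match", "best close match", "all
species barcodes") and two tree-based criteria (strict monophyly; the
revised cluster-membership criterion that does not require monophyly) are
evaluated in a leave-one-out protocol: each library sequence in turn is
treated as the query and its own entry is excluded from the candidate set.

Verdicts are ``success``, ``ambiguous``, ``misidentified`` and — for the
threshold-bearing criteria — ``no_match`` when no library sequence falls
within the distance threshold.  Ties at the minimum distance are kept as a
set (no arbitrary winner); a tied set mixing species yields ``ambiguous``.
Threshold comparisons are inclusive (distance ≤ threshold qualifies).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import dendropy
import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .io import AMBIGUITY_CODE, BASES, BarcodeRecord

Verdict = Literal["success", "ambiguous", "misidentified", "no_match"]

#: Floating-point slack for distance ties and threshold comparisons.  All
#: p-distances are ratios of small integers, so exact ties are real; the
#: epsilon only guards against non-associative float summation.
TIE_EPS = 1e-12


@dataclass
class IdentificationOutcome:
    query_id: str
    criterion: str
    verdict: Verdict
    threshold: float | None = None
    evidence: list[str] = field(default_factory=list)


def _candidate_distances(
    query_idx: int, m: DistanceMatrix
) -> list[tuple[int, float]]:
    out = []
    for j in range(m.n):
        if j == query_idx:
            continue
        v = m.d[query_idx, j]
        if not math.isnan(v):
            out.append((j, v))
    return out


def _verdict_from_best_set(
    query: BarcodeRecord, best: list[BarcodeRecord]
) -> Verdict:
    species = {r.species for r in best}
    if species == {query.species}:
        return "success"
    if query.species in species:
        return "ambiguous"
    return "misidentified"


def best_match(
    query_id: str, m: DistanceMatrix, records: Sequence[BarcodeRecord]
) -> IdentificationOutcome:
    """Identify by the species of the closest library sequence(s).

    All sequences tied at the minimum distance count: success if the tied
    set is purely conspecific, misidentified if purely allospecific,
    ambiguous if mixed.
    """
    if m.n < 2:
        raise ValueError("best_match requires a library of at least 2 sequences")
    qi = m.index_of(query_id)
    query = records[qi]
    cands = _candidate_distances(qi, m)
    if not cands:
        raise ValueError(f"query {query_id!r} has no defined distances")
    dmin = min(v for _, v in cands)
    best = [records[j] for j, v in cands if v <= dmin + TIE_EPS]
    return IdentificationOutcome(
        query_id=query_id,
        criterion="best_match",
        verdict=_verdict_from_best_set(query, best),
        evidence=[r.id for r in best],
    )


def best_close_match(
    query_id: str,
    m: DistanceMatrix,
    records: Sequence[BarcodeRecord],
    threshold: float,
) -> IdentificationOutcome:
    """Best match restricted to candidates within the distance threshold."""
    if m.n < 2:
        raise ValueError("best_close_match requires a library of at least 2 sequences")
    qi = m.index_of(query_id)
    query = records[qi]
    cands = [(j, v) for j, v in _candidate_distances(qi, m) if v <= threshold + TIE_EPS]
    if not cands:
        return IdentificationOutcome(
            query_id=query_id, criterion="best_close_match",
            verdict="no_match", threshold=threshold,
        )
    dmin = min(v for _, v in cands)
    best = [records[j] for j, v in cands if v <= dmin + TIE_EPS]
    return IdentificationOutcome(
        query_id=query_id,
        criterion="best_close_match",
        verdict=_verdict_from_best_set(query, best),
        threshold=threshold,
        evidence=[r.id for r in best],
    )


def all_species_barcodes(
    query_id: str,
    m: DistanceMatrix,
    records: Sequence[BarcodeRecord],
    threshold: float,
) -> IdentificationOutcome:
    """Identify by the full set of library sequences within the threshold.

    Success requires that set to be non-empty, purely conspecific, and to
    contain *every* conspecific of the query — the strictest reading of the
    premise that conspecifics are mutually more similar than any of them is
    to a heterospecific.
    """
    if m.n < 2:
        raise ValueError(
            "all_species_barcodes requires a library of at least 2 sequences"
        )
    qi = m.index_of(query_id)
    query = records[qi]
    within = [
        records[j]
        for j, v in _candidate_distances(qi, m)
        if v <= threshold + TIE_EPS
    ]
    if not within:
        return IdentificationOutcome(
            query_id=query_id, criterion="all_species_barcodes",
            verdict="no_match", threshold=threshold,
        )
    conspecifics = {
        r.id for r in records if r.species == query.species and r.id != query_id
    }
    within_ids = {r.id for r in within}
    species = {r.species for r in within}
    if species == {query.species} and conspecifics <= within_ids:
        verdict: Verdict = "success"
    elif query.species not in species:
        verdict = "misidentified"
    else:
        verdict = "ambiguous"
    return IdentificationOutcome(
        query_id=query_id,
        criterion="all_species_barcodes",
        verdict=verdict,
        threshold=threshold,
        evidence=sorted(within_ids),
    )


# ---------------------------------------------------------------------------
# tree-based criteria


def _species_tips(records: Sequence[BarcodeRecord]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for r in records:
        out.setdefault(r.species, set()).add(r.id)
    return out


def _leaf_sets(tree: dendropy.Tree) -> dict:
    """Map each node to the set of tip labels below it."""
    sets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = {node.taxon.label}
        else:
            s: set[str] = set()
            for c in node.child_nodes():
                s |= sets[c]
            sets[node] = s
    return sets


def _check_tips(tree: dendropy.Tree, records: Sequence[BarcodeRecord]) -> None:
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ids = {r.id for r in records}
    if tips != ids:
        raise ValueError(
            f"tree tips and record ids differ (only in tree: {sorted(tips - ids)[:5]}, "
            f"only in records: {sorted(ids - tips)[:5]})"
        )


def tree_id_hebert(
    tree: dendropy.Tree, records: Sequence[BarcodeRecord]
) -> list[IdentificationOutcome]:
    """Strict-monophyly tree identification.

    Every member of a species is a success iff the species forms an
    exclusive clade; members of non-monophyletic species are all
    misidentified; singletons are ambiguous (nothing conspecific to
    cluster with).  Monophyly is assessed on bipartitions, so the
    placement of the root cannot split a species.
    """
    _check_tips(tree, records)
    leaf_sets = _leaf_sets(tree)
    all_tips = frozenset(r.id for r in records)
    clades = set(map(frozenset, leaf_sets.values()))
    clades |= {all_tips - c for c in clades}
    outcomes = []
    for sp, tips in _species_tips(records).items():
        if len(tips) == 1:
            verdict: Verdict = "ambiguous"
        elif frozenset(tips) in clades:
            verdict = "success"
        else:
            verdict = "misidentified"
        outcomes.extend(
            IdentificationOutcome(query_id=t, criterion="tree_hebert", verdict=verdict)
            for t in sorted(tips)
        )
    return outcomes


def tree_id_meier(
    tree: dendropy.Tree, records: Sequence[BarcodeRecord]
) -> list[IdentificationOutcome]:
    """Cluster-membership tree identification (monophyly not required).

    Each query is assessed with its own tip logically removed: the cluster
    it joined is the set of remaining tips under its parent node.  Success
    when that cluster is purely conspecific; misidentified when purely
    allospecific; mixed clusters, and species with only one or two
    sequences, are ambiguous.
    """
    _check_tips(tree, records)
    leaf_sets = _leaf_sets(tree)
    species_of = {r.id: r.species for r in records}
    counts = Counter(species_of.values())
    leaf_by_label = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    outcomes = []
    for r in records:
        if counts[r.species] <= 2:
            outcomes.append(
                IdentificationOutcome(
                    query_id=r.id, criterion="tree_meier", verdict="ambiguous"
                )
            )
            continue
        node = leaf_by_label[r.id].parent_node
        # after pruning the query its parent collapses; walk up until some
        # other tip remains in the cluster
        cluster = leaf_sets[node] - {r.id}
        while not cluster and node.parent_node is not None:
            node = node.parent_node
            cluster = leaf_sets[node] - {r.id}
        cluster_species = {species_of[t] for t in cluster}
        if cluster_species == {r.species}:
            verdict: Verdict = "success"
        elif r.species in cluster_species:
            verdict = "ambiguous"
        else:
            verdict = "misidentified"
        outcomes.append(
            IdentificationOutcome(
                query_id=r.id, criterion="tree_meier", verdict=verdict,
                evidence=sorted(cluster),
            )
        )
    return outcomes


# ---------------------------------------------------------------------------
# consensus barcodes


def consensus_barcode(records: Sequence[BarcodeRecord]) -> str:
    """Per-site strict-majority consensus of one species' sequences.

    A gap wins a site only on strict majority of all counted characters;
    otherwise the majority base wins, with ties encoded as the IUPAC
    ambiguity code of the tied bases.  Ambiguity codes in the input are
    treated as missing at that site.
    """
    if not records:
        raise ValueError("consensus_barcode requires at least one record")
    length = len(records[0].sequence)
    out = []
    for j in range(length):
        col = [r.sequence[j] for r in records]
        counts = Counter(c for c in col if c in BASES or c == "-")
        if not counts:
            out.append("N")
            continue
        total = sum(counts.values())
        if counts.get("-", 0) * 2 > total:
            out.append("-")
            continue
        base_counts = {b: counts[b] for b in BASES if counts.get(b)}
        if not base_counts:
            out.append("-")
            continue
        top = max(base_counts.values())
        tied = frozenset(b for b, c in base_counts.items() if c == top)
        out.append(AMBIGUITY_CODE[tied])
    return "".join(out)


def consensus_uniqueness(
    records: Sequence[BarcodeRecord],
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Species consensus barcodes plus any pairs sharing an identical consensus."""
    by_species: dict[str, list[BarcodeRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    consensus = {sp: consensus_barcode(rs) for sp, rs in by_species.items()}
    clashes = []
    species = sorted(consensus)
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            if consensus[a] == consensus[b]:
                clashes.append((a, b))
    return consensus, clashes


# ---------------------------------------------------------------------------
# aggregate report


@dataclass
class IdentificationReport:
    """Leave-one-out verdict percentages per criterion and threshold."""

    counts: pd.DataFrame  # columns: criterion, threshold, verdict, n, percent
    n_queries: int
    outcomes: list[IdentificationOutcome]

    def percent(
        self, criterion: str, verdict: str, threshold: float | None = None
    ) -> float:
        df = self.counts
        sel = (df["criterion"] == criterion) & (df["verdict"] == verdict)
        if threshold is None:
            sel &= df["threshold"].isna()
        else:
            sel &= np.isclose(df["threshold"].astype(float), threshold)
        rows = df[sel]
        return float(rows["percent"].sum()) if len(rows) else 0.0

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def identification_report(
    records: Sequence[BarcodeRecord],
    m: DistanceMatrix,
    thresholds: Sequence[float],
    tree: dendropy.Tree | None = None,
) -> IdentificationReport:
    """Run every criterion over every record as a leave-one-out query.

    ``best_match`` is threshold-free and reported once; the two threshold
    criteria are reported per threshold; the tree criteria are included
    when a tree is supplied.
    """
    if len(records) < 2:
        raise ValueError("identification_report requires at least 2 records")
    outcomes: list[IdentificationOutcome] = []
    for r in records:
        outcomes.append(best_match(r.id, m, records))
        for t in thresholds:
            outcomes.append(best_close_match(r.id, m, records, t))
            outcomes.append(all_species_barcodes(r.id, m, records, t))
    if tree is not None:
        outcomes.extend(tree_id_hebert(tree, records))
        outcomes.extend(tree_id_meier(tree, records))

    n = len(records)
    rows = []
    groups: dict[tuple[str, float | None], Counter] = {}
    for o in outcomes:
        groups.setdefault((o.criterion, o.threshold), Counter())[o.verdict] += 1
    for (crit, thr), counter in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1] is not None, kv[0][1] or 0)
    ):
        for verdict in ("success", "ambiguous", "misidentified", "no_match"):
            c = counter.get(verdict, 0)
            rows.append(
                {
                    "criterion": crit,
                    "threshold": thr,
                    "verdict": verdict,
                    "n": c,
                    "percent": 100.0 * c / n,
                }
            )
    return IdentificationReport(
        counts=pd.DataFrame(rows), n_queries=n, outcomes=outcomes
    )


def outcomes_frame(outcomes: Sequence[IdentificationOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query": o.query_id,
                "criterion": o.criterion,
                "threshold": o.threshold,
                "verdict": o.verdict,
                "evidence": ",".join(o.evidence),
            }
            for o in outcomes
        ]
    )
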