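"""Pairwise p-distances and barcoding-gap statistics.

The p-distance between two aligned sequences is the proportion of differing
sites among the positions where *both* sequences carry an unambiguous base
(pairwise deletion: gaps and IUPAC ambiguity codes drop the site for that
pair only).  Pairs sharing fewer than ``min_overlap`` comparable sites are
flagged undefined and excluded from every downstream summary.

On top of the matrix this module computes the classic barcode-library
summaries: per-species / per-genus divergence tables, the percentile-based
distance threshold, global barcoding-gap histograms with the intra/inter
overlap interval, and the per-species local-gap table (maximum intra-specific
distance versus nearest-neighbour distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import BASES, BarcodeRecord, _check_equal_lengths

DEFAULT_MIN_OVERLAP = 300

_CODE = {b: i for i, b in enumerate(BASES)}


def _encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8; unambiguous bases 0-3, everything else -1."""
    return np.fromiter((_CODE.get(c, -1) for c in seq), dtype=np.int8, count=len(seq))


def p_distance(
    seq_a: str, seq_b: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """p-distance between two aligned sequences, or NaN if overlap is too short."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences have unequal lengths ({len(seq_a)} vs {len(seq_b)})"
        )
    a, b = _encode(seq_a), _encode(seq_b)
    shared = (a >= 0) & (b >= 0)
    n_shared = int(shared.sum())
    if n_shared < min_overlap:
        return math.nan
    diffs = int((a[shared] != b[shared]).sum())
    return diffs / n_shared


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix with per-pair overlap counts.

    ``d[i, j]`` is NaN for pairs whose shared unambiguous site count
    ``overlap[i, j]`` falls below ``min_overlap``.
    """

    ids: list[str]
    d: np.ndarray
    overlap: np.ndarray
    min_overlap: int

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, id_: str) -> int:
        return self.ids.index(id_)

    def defined(self) -> np.ndarray:
        """Boolean mask of defined off-diagonal pairs."""
        mask = ~np.isnan(self.d)
        np.fill_diagonal(mask, False)
        return mask

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(
            ids=list(ids),
            d=self.d[np.ix_(idx, idx)].copy(),
            overlap=self.overlap[np.ix_(idx, idx)].copy(),
            min_overlap=self.min_overlap,
        )

    def to_square_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    def to_long_tsv(self, path: str | Path) -> None:
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append(
                    {
                        "id1": self.ids[i],
                        "id2": self.ids[j],
                        "distance": self.d[i, j],
                        "overlap": int(self.overlap[i, j]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_square_tsv(
        cls, path: str | Path, min_overlap: int = DEFAULT_MIN_OVERLAP
    ) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        d = df.to_numpy(dtype=float)
        overlap = np.full_like(d, np.inf)
        return cls(ids=[str(c) for c in df.columns], d=d, overlap=overlap,
                   min_overlap=min_overlap)


def distance_matrix(
    records: Sequence[BarcodeRecord], min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """All-pairs p-distance matrix under pairwise deletion."""
    if len(records) < 2:
        raise ValueError("distance_matrix requires at least two records")
    _check_equal_lengths(records)
    enc = np.stack([_encode(r.sequence) for r in records])  # (n, L)
    valid = enc >= 0
    n = len(records)
    d = np.zeros((n, n))
    overlap = np.zeros((n, n), dtype=np.int64)
    overlap[np.diag_indices(n)] = valid.sum(axis=1)
    for i in range(n):
        shared = valid[i] & valid[i + 1 :]  # (n-i-1, L)
        n_shared = shared.sum(axis=1)
        diffs = ((enc[i] != enc[i + 1 :]) & shared).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dij = np.where(n_shared > 0, diffs / np.maximum(n_shared, 1), np.nan)
        dij = np.where(n_shared < min_overlap, np.nan, dij)
        d[i, i + 1 :] = dij
        d[i + 1 :, i] = dij
        overlap[i, i + 1 :] = n_shared
        overlap[i + 1 :, i] = n_shared
    return DistanceMatrix(
        ids=[r.id for r in records], d=d, overlap=overlap, min_overlap=min_overlap
    )


# ---------------------------------------------------------------------------
# group-wise summaries


def _pair_values(
    m: DistanceMatrix, idx_a: Sequence[int], idx_b: Sequence[int] | None = None
) -> np.ndarray:
    """Defined distances over unordered pairs within idx_a, or across a×b."""
    vals = []
    if idx_b is None:
        for ii, i in enumerate(idx_a):
            for j in idx_a[ii + 1 :]:
                v = m.d[i, j]
                if not math.isnan(v):
                    vals.append(v)
    else:
        for i in idx_a:
            for j in idx_b:
                v = m.d[i, j]
                if not math.isnan(v):
                    vals.append(v)
    return np.asarray(vals)


def _species_indices(records: Sequence[BarcodeRecord]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        out.setdefault(r.species, []).append(i)
    return out


def intra_specific_distances(
    m: DistanceMatrix, records: Sequence[BarcodeRecord]
) -> np.ndarray:
    """Pooled defined distances over all conspecific pairs."""
    vals = [
        _pair_values(m, idx) for idx in _species_indices(records).values()
        if len(idx) >= 2
    ]
    return np.concatenate([v for v in vals if v.size] or [np.empty(0)])


def inter_specific_distances(
    m: DistanceMatrix,
    records: Sequence[BarcodeRecord],
    within: Literal["all", "genus", "family", "higher_taxon"] = "all",
) -> np.ndarray:
    """Pooled defined distances over heterospecific pairs.

    ``within='genus'`` restricts to congeneric pairs (the intra-generic
    inter-specific divergences of the divergence table); 'family' and
    'higher_taxon' likewise; 'all' pools every heterospecific pair.
    """
    vals = []
    for i in range(m.n):
        for j in range(i + 1, m.n):
            ri, rj = records[i], records[j]
            if ri.species == rj.species:
                continue
            if within == "genus" and ri.genus != rj.genus:
                continue
            if within == "family" and ri.family != rj.family:
                continue
            if within == "higher_taxon" and ri.higher_taxon != rj.higher_taxon:
                continue
            v = m.d[i, j]
            if not math.isnan(v):
                vals.append(v)
    return np.asarray(vals)


@dataclass
class DivergenceSummary:
    """Min/mean/max divergence tables within species and within genera.

    ``per_species`` has one row per species (NaN rows for singletons);
    ``per_genus`` one row per genus with ≥2 species (inter-specific pairs
    only).  ``overall`` pools all intra-specific and all intra-generic
    inter-specific distances.
    """

    per_species: pd.DataFrame
    per_genus: pd.DataFrame
    overall: dict[str, dict[str, float]]

    def to_tsv(self, species_path: str | Path, genus_path: str | Path) -> None:
        self.per_species.to_csv(species_path, sep="\t", index=False)
        self.per_genus.to_csv(genus_path, sep="\t", index=False)


def _mmm(vals: np.ndarray) -> tuple[float, float, float]:
    if vals.size == 0:
        return (math.nan, math.nan, math.nan)
    return float(vals.min()), float(vals.mean()), float(vals.max())


def divergence_summary(
    m: DistanceMatrix, records: Sequence[BarcodeRecord]
) -> DivergenceSummary:
    """Divergence table: intra-specific and intra-generic min/mean/max."""
    sp_rows = []
    species_seen = []
    for sp, idx in _species_indices(records).items():
        species_seen.append(sp)
        vals = _pair_values(m, idx) if len(idx) >= 2 else np.empty(0)
        mn, me, mx = _mmm(vals)
        sp_rows.append(
            {"species": sp, "n_sequences": len(idx), "min": mn, "mean": me, "max": mx}
        )

    genus_idx: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        genus_idx.setdefault(r.genus, []).append(i)
    gn_rows = []
    for gn, idx in genus_idx.items():
        n_species = len({records[i].species for i in idx})
        vals = []
        for ii, i in enumerate(idx):
            for j in idx[ii + 1 :]:
                if records[i].species != records[j].species:
                    v = m.d[i, j]
                    if not math.isnan(v):
                        vals.append(v)
        mn, me, mx = _mmm(np.asarray(vals))
        gn_rows.append(
            {"genus": gn, "n_species": n_species, "min": mn, "mean": me, "max": mx}
        )

    overall = {
        "intra_specific": dict(
            zip(("min", "mean", "max"), _mmm(intra_specific_distances(m, records)))
        ),
        "intra_generic": dict(
            zip(
                ("min", "mean", "max"),
                _mmm(inter_specific_distances(m, records, within="genus")),
            )
        ),
    }
    return DivergenceSummary(
        per_species=pd.DataFrame(sp_rows),
        per_genus=pd.DataFrame(gn_rows),
        overall=overall,
    )


def percentile_threshold(
    m: DistanceMatrix, records: Sequence[BarcodeRecord], q: float = 95.0
) -> float:
    """q-th percentile of the pooled intra-specific pairwise distances.

    Linear interpolation between order statistics.  The 95th percentile is
    the classic data-driven identification threshold: the distance below
    which 95% of all conspecific pairwise distances fall.
    """
    vals = intra_specific_distances(m, records)
    if vals.size == 0:
        raise ValueError("no defined intra-specific pairwise distances")
    return float(np.percentile(vals, q, method="linear"))


# ---------------------------------------------------------------------------
# barcoding gaps


@dataclass
class GapReport:
    """Global barcoding-gap summary at one grouping level.

    The overlap interval is [min inter-specific, max intra-specific]; a
    global gap exists iff the interval is empty (max intra < min inter).
    ``overlap_fraction`` is the share of all defined pairwise distances in
    scope that fall inside the closed interval.
    """

    grouping: str
    group: str | None
    bin_edges: np.ndarray
    intra_hist: np.ndarray
    inter_hist: np.ndarray
    overlap_interval: tuple[float, float]
    overlap_width: float
    overlap_fraction: float
    global_gap_present: bool
    n_intra: int
    n_inter: int
    trim: float = 0.0

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "group": self.group,
            "bin_edges": self.bin_edges.tolist(),
            "intra_hist": self.intra_hist.tolist(),
            "inter_hist": self.inter_hist.tolist(),
            "overlap_interval": list(self.overlap_interval),
            "overlap_width": self.overlap_width,
            "overlap_fraction": self.overlap_fraction,
            "global_gap_present": self.global_gap_present,
            "n_intra": self.n_intra,
            "n_inter": self.n_inter,
            "trim": self.trim,
        }


def _gap_from_values(
    intra: np.ndarray,
    inter: np.ndarray,
    grouping: str,
    group: str | None,
    bin_width: float,
    trim: float,
) -> GapReport:
    if trim > 0:
        # Trimmed ("90%") variant: drop the extreme trim fraction from each
        # tail of each class before locating the interval.  Interpretation of
        # the partial-overlap statistic; labelled via the ``trim`` field.
        lo, hi = 100 * trim, 100 * (1 - trim)
        intra_t = intra[(intra >= np.percentile(intra, lo)) & (intra <= np.percentile(intra, hi))] if intra.size else intra
        inter_t = inter[(inter >= np.percentile(inter, lo)) & (inter <= np.percentile(inter, hi))] if inter.size else inter
    else:
        intra_t, inter_t = intra, inter
    max_intra = float(intra_t.max())
    min_inter = float(inter_t.min())
    lo_b, hi_b = min_inter, max_intra
    width = max(0.0, hi_b - lo_b)
    pooled = np.concatenate([intra, inter])
    if width > 0:
        frac = float(((pooled >= lo_b) & (pooled <= hi_b)).mean())
    else:
        frac = 0.0
    top = max(float(pooled.max()), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] < top:
        edges = np.append(edges, edges[-1] + bin_width)
    return GapReport(
        grouping=grouping,
        group=group,
        bin_edges=edges,
        intra_hist=np.histogram(intra, bins=edges)[0],
        inter_hist=np.histogram(inter, bins=edges)[0],
        overlap_interval=(lo_b, hi_b),
        overlap_width=width,
        overlap_fraction=frac,
        global_gap_present=width <= 0.0,
        n_intra=int(intra.size),
        n_inter=int(inter.size),
        trim=trim,
    )


def global_gap_report(
    m: DistanceMatrix,
    records: Sequence[BarcodeRecord],
    grouping: Literal["species", "genus", "family", "higher_taxon"] = "species",
    bin_width: float = 0.01,
    trim: float = 0.0,
) -> list[GapReport]:
    """Barcoding-gap histograms and overlap statistics.

    At ``grouping='species'`` a single dataset-wide report is returned
    (intra = conspecific pairs, inter = all heterospecific pairs).  At any
    coarser grouping one report per group is returned, with comparisons
    restricted to pairs inside that group; groups lacking an intra or an
    inter class are silently absent from the output.
    """
    reports: list[GapReport] = []
    if grouping == "species":
        intra = intra_specific_distances(m, records)
        inter = inter_specific_distances(m, records, within="all")
        if intra.size and inter.size:
            reports.append(
                _gap_from_values(intra, inter, grouping, None, bin_width, trim)
            )
        return reports

    attr = grouping
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault(getattr(r, attr), []).append(i)
    for g, idx in sorted(groups.items()):
        sub_records = [records[i] for i in idx]
        sub = m.submatrix([records[i].id for i in idx])
        intra = intra_specific_distances(sub, sub_records)
        inter = inter_specific_distances(sub, sub_records, within="all")
        if intra.size and inter.size:
            reports.append(
                _gap_from_values(intra, inter, grouping, g, bin_width, trim)
            )
    return reports


@dataclass
class LocalGapRow:
    """One species' local barcoding gap: max intra vs nearest neighbour."""

    species: str
    n_sequences: int
    max_intra: float
    nn_dist: float
    nearest_neighbour: str  # heterospecific species at minimum distance
    local_gap_present: bool


def local_gap_table(
    m: DistanceMatrix, records: Sequence[BarcodeRecord]
) -> list[LocalGapRow]:
    """Per-species maximum intra-specific vs nearest-neighbour distance.

    Species with a single sequence are omitted (their max intra-specific
    distance is undefined).  The nearest neighbour is the heterospecific
    sequence at minimum distance from any member of the species.
    """
    rows: list[LocalGapRow] = []
    sp_idx = _species_indices(records)
    for sp, idx in sp_idx.items():
        if len(idx) < 2:
            continue
        intra = _pair_values(m, idx)
        if intra.size == 0:
            continue
        others = [j for j, r in enumerate(records) if r.species != sp]
        nn_dist = math.inf
        nn_sp = ""
        for i in idx:
            for j in others:
                v = m.d[i, j]
                if not math.isnan(v) and v < nn_dist:
                    nn_dist = v
                    nn_sp = records[j].species
        if math.isinf(nn_dist):
            continue
        rows.append(
            LocalGapRow(
                species=sp,
                n_sequences=len(idx),
                max_intra=float(intra.max()),
                nn_dist=nn_dist,
                nearest_neighbour=nn_sp,
                local_gap_present=float(intra.max()) < nn_dist,
            )
        )
    return rows


def local_gap_frame(rows: Sequence[LocalGapRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])
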