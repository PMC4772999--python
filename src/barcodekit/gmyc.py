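"""Single-threshold GMYC species delimitation.

The generalized mixed Yule coalescent model locates the age T* on an
ultrametric tree at which branching switches from a between-species
diversification (Yule, pure-birth) process to within-species
coalescent-style branching.  Nodes older than the threshold are
speciation events; the lineages crossing the threshold define the
delimited *entities*, inside which the remaining (younger) nodes are
coalescences.

Likelihood.  Let the internal-node ages, ordered from the root down,
partition the tree into inter-node intervals.  Within an interval the
total branching rate is

    b = lambda_yule * k  +  lambda_coal * sum_j n_j (n_j - 1)

where ``k`` is the number of species-level (between-entity) lineages and
``n_j`` the number of lineages inside entity ``j``.  Above the threshold
every lineage is a species lineage (k = crossing lineages, all n_j = 1);
below it one species lineage per entity persists to the present (no
further speciation is observed) while the entities' internal lineages
coalesce.  The branching events form a single exponential race: an
interval of width ``w`` ending in a branching event contributes
``b exp(-b w)`` with the interval's combined rate, and the final
interval to the present contributes the survival factor ``exp(-b w)``.
The rate-scaling exponents of the general model are fixed at one (rate
linear in k, combinatorial in n_j).

Because candidate thresholds only matter through which nodes they
classify as speciations, the profile likelihood is maximised by scanning
the internal-node ages; for each candidate the two rates are fitted by
bounded maximisation of the (concave) log-likelihood.  The null model is
the same waiting-time likelihood with a single rate class over the whole
tree; the alternative reproduces it at the youngest-node threshold, so
the likelihood-ratio statistic is non-negative.  The LR is referred to a
chi-square distribution with 2 degrees of freedom (the second rate class
and the threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cluster import taxonomic_accuracy
from .io import BarcodeRecord
from .trees import ULTRAMETRIC_TOL, node_ages

#: Ages closer than this are treated as simultaneous events.
AGE_TOL = 1e-9

LRT_DF = 2


def branching_times(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> list[float]:
    """Internal-node ages of an ultrametric tree, sorted ascending.

    Ages are measured from the tips (age 0) upward; the largest value is
    the root age.
    """
    ages = node_ages(tree, tol)
    return sorted(a for node, a in ages.items() if not node.is_leaf())


def _tree_intervals(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL):
    """Precompute, for every internal node (potential event), its age and,
    for every inter-event interval, the branches crossing it.

    Returns (ages_desc, crossing) where ``ages_desc`` excludes the root
    event (the process starts with two lineages at the root age) and
    ``crossing[i]`` is the list of nodes whose subtending branch crosses
    interval i (between event i-1 and event i; interval 0 starts at the
    root age).  A final interval down to the present is appended.
    """
    ages = node_ages(tree, tol)
    internal = sorted(
        ((a, node) for node, a in ages.items() if not node.is_leaf()),
        key=lambda pair: pair[0],
        reverse=True,  # root first
    )
    root_age, root = internal[0]
    events = internal[1:]  # ages descending
    boundaries = [root_age] + [a for a, _ in events] + [0.0]
    # lineages crossing an interval (lower_age, upper_age): nodes whose own
    # age < lower boundary... a branch from parent (age ap) to node (age an)
    # crosses the interval iff an <= lower < upper <= ap.
    crossing: list[list[dendropy.Node]] = []
    all_nodes = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    for i in range(len(boundaries) - 1):
        upper, lower = boundaries[i], boundaries[i + 1]
        cross = [
            n
            for n in all_nodes
            if ages[n] <= lower + AGE_TOL and ages[n.parent_node] >= upper - AGE_TOL
        ]
        crossing.append(cross)
    return ages, root_age, [a for a, _ in events], boundaries, crossing


@dataclass
class GmycFit:
    """A fitted single-threshold GMYC model."""

    threshold_age: float
    lambda_yule: float
    lambda_coal: float
    logL_alt: float
    logL_null: float
    lr_stat: float
    p_value: float
    entities: list[list[str]]
    n_entities: int
    candidate_ages: list[float] = field(default_factory=list)
    profile_logL: list[float] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        return {
            "threshold_age": self.threshold_age,
            "lambda_yule": self.lambda_yule,
            "lambda_coal": self.lambda_coal,
            "logL_alt": self.logL_alt,
            "logL_null": self.logL_null,
            "lr_stat": self.lr_stat,
            "p_value": self.p_value,
            "n_entities": self.n_entities,
        }


def entities_at_threshold(
    tree: dendropy.Tree, threshold: float, tol: float = ULTRAMETRIC_TOL
) -> list[list[str]]:
    """Cut the tree at the given age: each lineage crossing it is an entity.

    Nodes with age >= threshold are treated as between-entity (speciation)
    nodes; each maximal subtree whose root is younger than the threshold
    forms one entity.  A threshold above the root age yields a single
    entity; one at or below zero yields one entity per tip.
    """
    ages = node_ages(tree, tol)
    entities: list[list[str]] = []

    def leaves_under(node) -> list[str]:
        return [lf.taxon.label for lf in node.leaf_iter()]

    def walk(node) -> None:
        if ages[node] < threshold - AGE_TOL or node.is_leaf():
            entities.append(leaves_under(node))
        else:
            for c in node.child_nodes():
                walk(c)

    root = tree.seed_node
    if ages[root] < threshold - AGE_TOL:
        return [leaves_under(root)]
    walk(root)
    return entities


def _interval_stats(
    boundaries: list[float],
    crossing: list[list],
    ages: Mapping,
    threshold: float,
):
    """Per-interval widths, rate coefficients and event flags.

    Yields (width, yule_coef, coal_coef, has_event) tuples, root-down.
    In intervals above the threshold every crossing lineage belongs to
    the diversification process (yule_coef = k, coal_coef = 0: entity
    stems have n_j = 1).  Below it, one species-level lineage per entity
    persists (yule_coef = number of entities) while the entities'
    internal lineages can coalesce (coal_coef = sum_j n_j (n_j - 1)).
    Every interval except the final one (which runs to the present) ends
    with a branching event; the root opens the process and is not itself
    an event.
    """
    n_int = len(boundaries) - 1
    entity_cache: dict = {}

    def entity_of(node):
        if node in entity_cache:
            return entity_cache[node]
        cur = node
        while cur.parent_node is not None and ages[cur.parent_node] < threshold - AGE_TOL:
            cur = cur.parent_node
        entity_cache[node] = cur
        return cur

    for i in range(n_int):
        upper, lower = boundaries[i], boundaries[i + 1]
        width = upper - lower
        lineages = crossing[i]
        if lower >= threshold - AGE_TOL:
            yule_coef = float(len(lineages))
            coal_coef = 0.0
        else:
            sizes: dict = {}
            for nd in lineages:
                e = entity_of(nd)
                sizes[e] = sizes.get(e, 0) + 1
            yule_coef = float(len(sizes))
            coal_coef = float(sum(n * (n - 1) for n in sizes.values()))
        yield width, yule_coef, coal_coef, i < n_int - 1


def _collect_terms(
    boundaries: list[float],
    crossing: list[list],
    ages: Mapping,
    threshold: float,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Event coefficients (A_e, B_e) and total rate-weighted times (TA, TB).

    logL(ly, lc) = sum_e log(ly A_e + lc B_e) - ly TA - lc TB.
    """
    A, B = [], []
    TA = TB = 0.0
    for width, yc, cc, has_event in _interval_stats(
        boundaries, crossing, ages, threshold
    ):
        TA += yc * width
        TB += cc * width
        if has_event:
            A.append(yc)
            B.append(cc)
    return np.asarray(A), np.asarray(B), TA, TB


def _maximise_two_rates(
    A: np.ndarray, B: np.ndarray, TA: float, TB: float
) -> tuple[float, float, float]:
    """Maximise the concave log-likelihood over the two non-negative rates.

    Projected Newton ascent on (lambda_yule, lambda_coal); the function is
    concave (sum of logs of linear forms minus a linear form), so the
    ascent converges from the single-rate starting point.  A rate whose
    coefficients vanish everywhere is pinned at zero.
    """
    m = len(A)
    if m == 0:
        return 0.0, 0.0, 0.0

    use_y = TA > 0 and A.any()
    use_c = TB > 0 and B.any()

    def logL(ly: float, lc: float) -> float:
        denom = ly * A + lc * B
        if np.any(denom <= 0):
            return -math.inf
        return float(np.log(denom).sum() - ly * TA - lc * TB)

    if not use_c:
        ly = m / TA  # pure Yule: analytic MLE
        return logL(ly, 0.0), ly, 0.0
    if not use_y:
        lc = m / TB
        return logL(0.0, lc), 0.0, lc

    start = m / (TA + TB)
    x = np.array([start, start], dtype=float)
    floor = 1e-12
    for _ in range(200):
        denom = x[0] * A + x[1] * B
        gy = float((A / denom).sum() - TA)
        gc = float((B / denom).sum() - TB)
        hyy = -float((A * A / denom**2).sum())
        hcc = -float((B * B / denom**2).sum())
        hyc = -float((A * B / denom**2).sum())
        det = hyy * hcc - hyc * hyc
        if abs(det) < 1e-300:
            break
        dy = -(hcc * gy - hyc * gc) / det
        dc = -(hyy * gc - hyc * gy) / det
        step = 1.0
        f0 = logL(*x)
        while step > 1e-8:
            cand = np.maximum([x[0] + step * dy, x[1] + step * dc], floor)
            if logL(*cand) >= f0 - 1e-15:
                break
            step /= 2.0
        new = np.maximum([x[0] + step * dy, x[1] + step * dc], floor)
        if np.max(np.abs(new - x) / np.maximum(new, floor)) < 1e-10:
            x = new
            break
        x = new
    return logL(*x), float(x[0]), float(x[1])


def _fit_at_threshold(
    boundaries: list[float],
    crossing: list[list],
    ages: Mapping,
    threshold: float,
) -> tuple[float, float, float]:
    """Profile log-likelihood and fitted rates for one candidate threshold."""
    A, B, TA, TB = _collect_terms(boundaries, crossing, ages, threshold)
    return _maximise_two_rates(A, B, TA, TB)


def gmyc_fit(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> GmycFit:
    """Fit the single-threshold GMYC model by profile-likelihood scan.

    Candidate thresholds are the internal-node ages (the likelihood is
    piecewise constant in the threshold between node ages).  Identical
    haplotypes should be collapsed beforehand: zero-length terminal
    branch pairs produce simultaneous events that carry no information
    about the rate shift.
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 3:
        raise ValueError("GMYC requires at least 3 tips")
    ages, root_age, event_ages, boundaries, crossing = _tree_intervals(tree, tol)

    internal_ages = sorted({root_age, *event_ages})
    candidates = sorted({a for a in internal_ages if a > AGE_TOL})
    if not candidates:
        raise ValueError("degenerate tree: all internal nodes at age zero")

    profile: list[float] = []
    fits: list[tuple[float, float]] = []
    for T in candidates:
        logL, lam_y, lam_c = _fit_at_threshold(boundaries, crossing, ages, T)
        profile.append(logL)
        fits.append((lam_y, lam_c))

    # null: a single Yule rate class across the whole tree == threshold at
    # (or below) the youngest internal node, with the coalescent class empty
    logL_null, _, _ = _fit_at_threshold(
        boundaries, crossing, ages, min(candidates) - 1.0
    )
    # guard: thresholds below every node classify all intervals as Yule
    best = int(np.argmax(profile))
    logL_alt = profile[best]
    T_star = candidates[best]
    lam_y, lam_c = fits[best]
    lr = 2.0 * (logL_alt - logL_null)
    if lr < 0 and lr > -1e-8:
        lr = 0.0
    entities = entities_at_threshold(tree, T_star, tol)
    return GmycFit(
        threshold_age=T_star,
        lambda_yule=lam_y,
        lambda_coal=lam_c,
        logL_alt=logL_alt,
        logL_null=logL_null,
        lr_stat=lr,
        p_value=float(chi2.sf(lr, LRT_DF)),
        entities=entities,
        n_entities=len(entities),
        candidate_ages=list(candidates),
        profile_logL=profile,
    )


def interval_log_likelihood(
    tree: dendropy.Tree,
    threshold: float,
    lambda_yule: float,
    lambda_coal: float,
    tol: float = ULTRAMETRIC_TOL,
) -> float:
    """Log-likelihood at fixed threshold and rates (no maximisation).

    Exposed for validation: a direct product of interval exponential
    densities must agree with the profile machinery.
    """
    ages, root_age, event_ages, boundaries, crossing = _tree_intervals(tree, tol)
    del root_age, event_ages
    logL = 0.0
    for width, yc, cc, has_event in _interval_stats(
        boundaries, crossing, ages, threshold
    ):
        b = lambda_yule * yc + lambda_coal * cc
        logL -= b * width
        if has_event:
            if b <= 0:
                return -math.inf
            logL += math.log(b)
    return logL


# ---------------------------------------------------------------------------
# partitioned analyses


@dataclass
class GmycPartitionReport:
    """Aggregate of independent GMYC fits over a dataset partition.

    Levels mirror the usual protocol: 'A' fits the entire library at
    once; 'B' fits each higher taxon independently; 'C' each family.
    Groups too small to fit (fewer than 3 collapsed haplotypes) are
    carried as a single entity each.
    """

    level: str
    fits: dict[str, GmycFit | None]
    entities: list[list[str]]  # expanded to original ids
    total_entities: int
    taxonomic_accuracy: float
    per_species_entities: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, ent in enumerate(self.entities):
            for id_ in ent:
                rows.append({"id": id_, "entity": gi})
        return pd.DataFrame(rows)


def _expand(entity: Sequence[str], membership: Mapping[str, Sequence[str]] | None):
    if membership is None:
        return list(entity)
    out: list[str] = []
    for rep in entity:
        out.extend(membership.get(rep, [rep]))
    return out


def gmyc_partitioned(
    records: Sequence[BarcodeRecord],
    trees: Mapping[str, dendropy.Tree],
    level: str = "A",
    n_recognized: int | None = None,
    membership: Mapping[str, Sequence[str]] | None = None,
    tol: float = ULTRAMETRIC_TOL,
) -> GmycPartitionReport:
    """Run independent GMYC fits per group and score against the taxonomy.

    ``trees`` maps group name -> ultrametric tree whose tips are record
    ids (or collapsed-haplotype representative ids, with ``membership``
    giving the expansion).  For level 'A' the single group should span all
    records; for 'B'/'C' groups follow the higher_taxon / family labels.
    Every record not covered by any tree (e.g. a monospecific group left
    out of the partition) is carried as one entity per group.

    Taxonomic accuracy counts species whose sequences map to exactly one
    entity containing only that species.
    """
    species_of = {r.id: r.species for r in records}
    if level == "A":
        group_of = {r.id: "all" for r in records}
    elif level == "B":
        group_of = {r.id: r.higher_taxon for r in records}
    elif level == "C":
        group_of = {r.id: r.family for r in records}
    else:
        raise ValueError(f"level must be 'A', 'B' or 'C', got {level!r}")

    groups: dict[str, list[str]] = {}
    for id_, g in group_of.items():
        groups.setdefault(g, []).append(id_)

    fits: dict[str, GmycFit | None] = {}
    entities: list[list[str]] = []
    warnings: list[str] = []
    for g, ids in sorted(groups.items()):
        tree = trees.get(g)
        if tree is None:
            group_species = {species_of[i] for i in ids}
            if len(group_species) == 1:
                # monospecific group excluded from tree inference: one entity
                warnings.append(
                    f"group {g!r}: monospecific, no tree; carried as one entity"
                )
                entities.append(list(ids))
                fits[g] = None
                continue
            raise ValueError(f"no tree supplied for multi-species group {g!r}")
        n_tips = sum(1 for _ in tree.leaf_node_iter())
        if n_tips < 3:
            warnings.append(
                f"group {g!r}: only {n_tips} haplotypes; carried as a single entity"
            )
            tipset: list[str] = []
            for lf in tree.leaf_node_iter():
                tipset.extend(_expand([lf.taxon.label], membership))
            entities.append(tipset)
            fits[g] = None
            continue
        fit = gmyc_fit(tree, tol)
        fits[g] = fit
        for ent in fit.entities:
            entities.append(_expand(ent, membership))

    per_species: dict[str, set[int]] = {}
    entity_species: list[set[str]] = []
    for gi, ent in enumerate(entities):
        sps = {species_of[i] for i in ent}
        entity_species.append(sps)
        for sp in sps:
            per_species.setdefault(sp, set()).add(gi)
    all_species = {r.species for r in records}
    if n_recognized is None:
        n_recognized = len(all_species)
    n_perfect = sum(
        1
        for sp, ents in per_species.items()
        if len(ents) == 1 and entity_species[next(iter(ents))] == {sp}
    )
    return GmycPartitionReport(
        level=level,
        fits=fits,
        entities=entities,
        total_entities=len(entities),
        taxonomic_accuracy=taxonomic_accuracy(n_perfect, n_recognized),
        per_species_entities={sp: len(ents) for sp, ents in per_species.items()},
        warnings=warnings,
    )
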