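"""Synthetic barcode libraries with known truth.

The generator composes a Yule (pure-birth) species tree with independent
Kingman-coalescent genealogies inside each species, grafted at the species
tips so the full gene tree stays ultrametric, then evolves sequences along
it under a reversible substitution model (JC69, K2P or HKY).  Branch
lengths are in expected substitutions per site throughout.

Default parameters emulate a mitochondrial barcode reference library for
a moderately old radiation: 663-bp sequences, within-species divergences
of roughly 0-17% and between-species (congeneric) divergences of roughly
3-24%.  Presets construct the qualitative situations the evaluation
machinery must distinguish:

``clean_gap``
    every species' maximum intra-specific distance is below the dataset's
    minimum inter-specific distance (a global barcoding gap);
``overlapping``
    at least one species' intra-specific variation exceeds some
    heterospecific distance (no global gap);
``paraphyly``
    one species label spans two non-sister clades (injected by label
    manipulation so the truth stays exact);
``singletons``
    at least one species is represented by a single sequence.

Each preset's property is *verified* on the realised distance matrix and
generation retries with fresh sub-seeds (bounded) until it holds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .distances import distance_matrix
from .errors import ScenarioError
from .io import BASES, BarcodeRecord
from .trees import is_ultrametric

Preset = Literal["clean_gap", "overlapping", "paraphyly", "singletons"]

MAX_RETRIES = 60


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic barcode library.

    ``birth_rate`` is the speciation rate of the Yule species tree (per
    substitution unit of time); ``coal_scale`` is the expected pairwise
    within-species coalescence time, so the expected conspecific path
    length between two tips is about ``2 * coal_scale`` substitutions per
    site.  ``n_individuals`` may be a constant or one count per species.
    """

    n_species: int = 5
    n_individuals: int | tuple[int, ...] = 4
    seq_length: int = 663
    birth_rate: float = 12.0
    coal_scale: float = 0.04
    model: Literal["JC69", "K2P", "HKY"] = "JC69"
    kappa: float = 4.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    preset: Preset | None = None

    def individuals(self) -> list[int]:
        if isinstance(self.n_individuals, int):
            return [self.n_individuals] * self.n_species
        if len(self.n_individuals) != self.n_species:
            raise ValueError("n_individuals must be constant or one per species")
        return list(self.n_individuals)

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.birth_rate <= 0 or self.coal_scale <= 0:
            raise ValueError("rates must be positive")
        if any(n < 1 for n in self.individuals()):
            raise ValueError("each species needs at least one individual")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated library."""

    species_of: dict[str, str]
    species_tree_newick: str
    gene_tree_newick: str
    preset: Preset | None
    diagnostics: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "species_of": self.species_of,
                    "species_tree_newick": self.species_tree_newick,
                    "gene_tree_newick": self.gene_tree_newick,
                    "preset": self.preset,
                    "diagnostics": self.diagnostics,
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# tree simulation


def _new_tree() -> dendropy.Tree:
    return dendropy.Tree(taxon_namespace=dendropy.TaxonNamespace())


def simulate_species_tree(
    n_species: int, birth_rate: float, seed: int | np.random.Generator
) -> dendropy.Tree:
    """Ultrametric Yule tree with ``n_species`` tips.

    Waiting times between speciations are Exponential(k * birth_rate)
    with k the current number of lineages; the tree is returned with tip
    labels ``sp1..spK`` and depth equal to the simulated time from the
    first split to the present.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    tree = _new_tree()
    tips = [tree.seed_node]
    tree.seed_node.edge.length = 0.0
    depth = 0.0
    pending = {tree.seed_node: 0.0}  # node -> time of its birth
    while len(tips) < n_species:
        k = len(tips)
        depth += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        parent = tips.pop(idx)
        parent.edge.length = depth - pending.pop(parent)
        children = []
        for _ in range(2):
            c = dendropy.Node()
            parent.add_child(c)
            pending[c] = depth
            children.append(c)
        tips.extend(children)
    # grow all open lineages to the present: the waiting time to the
    # (K+1)-th split, Exponential(K * birth).  By memorylessness this makes
    # the tree a stationary snapshot of a Yule process observed with K
    # extant lineages — the correct null for branching-rate tests; for
    # K=2 the split age is then Exponential(2 * birth_rate).
    height = depth + rng.exponential(1.0 / (len(tips) * birth_rate))
    for node in tips:
        node.edge.length = height - pending.pop(node)
    for i, node in enumerate(tips, start=1):
        taxon = tree.taxon_namespace.new_taxon(label=f"sp{i}")
        node.taxon = taxon
    return tree


def simulate_coalescent(
    n_tips: int, coal_scale: float, rng: np.random.Generator, labels: Sequence[str]
) -> tuple[dendropy.Node, float]:
    """Kingman coalescent genealogy of ``n_tips`` contemporaneous lineages.

    Pairwise coalescence times are Exponential with mean ``coal_scale``
    (each pair coalesces at rate 1/coal_scale).  Returns the root node of
    the genealogy (a free-standing subtree, tips labelled) and its depth.
    """
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd._label = lab
        nd._age = 0.0
        nodes.append(nd)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        rate = k * (k - 1) / 2.0 / coal_scale
        t += rng.exponential(1.0 / rate)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = dendropy.Node()
        parent._age = t
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = t - child._age
        nodes.append(parent)
    root = nodes[0]
    return root, getattr(root, "_age", 0.0)


def simulate_gene_trees(
    species_tree: dendropy.Tree,
    n_individuals: Sequence[int],
    coal_scale: float,
    seed: int | np.random.Generator,
) -> dendropy.Tree:
    """Graft per-species coalescent genealogies onto the species tree.

    Each species tip is replaced by a coalescent genealogy of its
    individuals whose root sits at the species tip; the species-tip
    branch is shortened by the genealogy depth so the composite tree
    remains ultrametric.  Requires every species-tip branch to be longer
    than the simulated within-species depth; the depth is resampled
    (bounded retries) when it is not.

    Tips are labelled ``sp<i>_<j>``.
    """
    rng = np.random.default_rng(seed)
    gene = species_tree.clone(depth=1)
    species_tips = list(gene.leaf_node_iter())
    label_of = {t.taxon.label: t for t in species_tips}
    for sp_i, n_i in enumerate(n_individuals, start=1):
        sp_label = f"sp{sp_i}"
        tip = label_of[sp_label]
        labels = [f"{sp_label}_{j}" for j in range(1, n_i + 1)]
        if n_i == 1:
            tip._new_label = labels[0]
            continue
        budget = tip.edge.length or 0.0
        subroot = depth = None
        for _ in range(MAX_RETRIES):
            subroot, depth = simulate_coalescent(n_i, coal_scale, rng, labels)
            if depth < budget:
                break
        else:
            raise ScenarioError(
                f"within-species genealogy of {sp_label} ({depth:.4f}) never fit "
                f"inside its terminal branch ({budget:.4f}); lower coal_scale "
                f"or birth_rate"
            )
        parent = tip.parent_node
        if parent is None:  # single-species tree: genealogy is the whole tree
            gene = dendropy.Tree(seed_node=subroot,
                                 taxon_namespace=dendropy.TaxonNamespace())
            subroot.edge.length = 0.0
            break
        parent.remove_child(tip)
        parent.add_child(subroot)
        subroot.edge.length = budget - depth
    # materialise taxa for all new tips
    ns = gene.taxon_namespace
    for leaf in gene.leaf_node_iter():
        label = getattr(leaf, "_new_label", None) or getattr(leaf, "_label", None) \
            or (leaf.taxon.label if leaf.taxon else None)
        leaf.taxon = ns.new_taxon(label=label) if (
            leaf.taxon is None or leaf.taxon.label != label
        ) else leaf.taxon
    return gene


# ---------------------------------------------------------------------------
# sequence evolution


def _rate_matrix(
    model: str, kappa: float, freqs: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised instantaneous rate matrix (expected 1 substitution/unit)."""
    pi = np.asarray(freqs, dtype=float)
    Q = np.ones((4, 4))
    if model == "JC69":
        pi = np.full(4, 0.25)
    if model in ("K2P", "HKY"):
        # transitions: A<->G (0,2), C<->T (1,3)
        for i, j in ((0, 2), (1, 3)):
            Q[i, j] = Q[j, i] = kappa
        if model == "K2P":
            pi = np.full(4, 0.25)
    Q = Q * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu, pi


def evolve_sequences(
    tree: dendropy.Tree,
    seq_length: int,
    model: str = "JC69",
    kappa: float = 4.0,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Evolve sequences along the tree; returns tip label -> sequence.

    The root sequence is drawn from the model's equilibrium frequencies
    and substitutions accumulate site-independently along each branch via
    the transition matrix exp(Q t).  Under JC69 the expected p-distance of
    two tips at path length t is (3/4)(1 - exp(-4 t / 3)).
    """
    rng = np.random.default_rng(seed)
    Q, pi = _rate_matrix(model, kappa, base_freqs)
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(4, size=seq_length, p=pi)
    out: dict[str, str] = {}
    base_arr = np.array(list(BASES))
    pmat_cache: dict[float, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            seq = states[id(root)]
        else:
            t = node.edge.length or 0.0
            P = pmat_cache.get(t)
            if P is None:
                P = expm(Q * t)
                P = np.clip(P, 0.0, None)
                P /= P.sum(axis=1, keepdims=True)
                pmat_cache[t] = P
            parent_seq = states[id(node.parent_node)]
            seq = np.empty(seq_length, dtype=np.int64)
            for s in range(4):
                idx = np.flatnonzero(parent_seq == s)
                if idx.size:
                    seq[idx] = rng.choice(4, size=idx.size, p=P[s])
            states[id(node)] = seq
        if node.is_leaf():
            out[node.taxon.label] = "".join(base_arr[seq])
        states[id(node)] = seq
    return out


# ---------------------------------------------------------------------------
# scenarios


def _taxonomy_for(species_labels: Sequence[str]) -> dict[str, tuple[str, str, str]]:
    """Assign genus/family/higher-taxon labels by blocks of species.

    Species are grouped pairwise into genera, genera pairwise into
    families, and families pairwise into higher taxa — a simple nested
    taxonomy sufficient to exercise every grouping level.
    """
    out = {}
    for i, sp in enumerate(species_labels):
        out[sp] = (
            f"genus{i // 2 + 1}",
            f"family{i // 4 + 1}",
            f"taxon{i // 8 + 1}",
        )
    return out


def _records_from(
    seqs: dict[str, str], species_of: dict[str, str]
) -> list[BarcodeRecord]:
    taxonomy = _taxonomy_for(sorted(set(species_of.values())))
    records = []
    for tip in sorted(seqs):
        sp = species_of[tip]
        genus, family, taxon = taxonomy[sp]
        records.append(
            BarcodeRecord(
                id=tip, species=sp, genus=genus, family=family,
                higher_taxon=taxon, sequence=seqs[tip],
            )
        )
    return records


def _intra_inter(records: list[BarcodeRecord]) -> tuple[float, float]:
    """Realised (max intra-specific, min inter-specific) p-distances."""
    m = distance_matrix(records, min_overlap=1)
    max_intra = -math.inf
    min_inter = math.inf
    for i in range(m.n):
        for j in range(i + 1, m.n):
            v = m.d[i, j]
            if records[i].species == records[j].species:
                max_intra = max(max_intra, v)
            else:
                min_inter = min(min_inter, v)
    return max_intra, min_inter


def _overlap_exists(records: list[BarcodeRecord]) -> bool:
    """True when some species' max intra exceeds some heterospecific distance."""
    m = distance_matrix(records, min_overlap=1)
    by_sp: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_sp.setdefault(r.species, []).append(i)
    for sp, idx in by_sp.items():
        if len(idx) < 2:
            continue
        mx = max(m.d[i, j] for ii, i in enumerate(idx) for j in idx[ii + 1 :])
        for i in idx:
            for j in range(m.n):
                if records[j].species != sp and m.d[i, j] < mx:
                    return True
    return False


def _non_sister_species_pair(species_tree: dendropy.Tree) -> tuple[str, str]:
    """Pick two species that are not sister taxa (preferring a distant pair)."""
    pdm = species_tree.phylogenetic_distance_matrix()
    tips = [lf.taxon for lf in species_tree.leaf_node_iter()]
    sisters = set()
    for leaf in species_tree.leaf_node_iter():
        sibs = [
            c.taxon.label
            for c in leaf.parent_node.child_nodes()
            if c.is_leaf() and c is not leaf
        ]
        for s in sibs:
            sisters.add(frozenset((leaf.taxon.label, s)))
    best, best_d = None, -1.0
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            if frozenset((a.label, b.label)) in sisters:
                continue
            d = pdm.patristic_distance(a, b)
            if d > best_d:
                best, best_d = (a.label, b.label), d
    if best is None:
        raise ScenarioError("species tree has no non-sister pair")
    return best


_PRESET_OVERRIDES: dict[str, dict] = {
    "clean_gap": {"coal_scale": 0.003, "birth_rate": 2.0},
    "overlapping": {"coal_scale": 0.08, "birth_rate": 30.0},
    "paraphyly": {"coal_scale": 0.003, "birth_rate": 2.0},
    "singletons": {"coal_scale": 0.003, "birth_rate": 2.0},
}

#: clean_gap demands species crowns much shallower than species splits:
#: the youngest between-species node must be at least this many times
#: older than the oldest within-species crown on the realised gene tree.
SEPARATION_FACTOR = 6.0

#: clean_gap also demands homogeneously shallow crowns: no species crown
#: deeper than this multiple of the expected pairwise coalescence time
#: (the Kingman tail otherwise hands single species a two-rate look).
CROWN_DEPTH_FACTOR = 5.0


def _crown_split_separation(gene_tree: dendropy.Tree) -> tuple[float, float]:
    """(max within-species crown age, min between-species node age)."""
    from .trees import node_ages

    ages = node_ages(gene_tree)
    max_crown, min_split = 0.0, math.inf
    for node, a in ages.items():
        if node.is_leaf():
            continue
        species = {
            lf.taxon.label.rsplit("_", 1)[0] for lf in node.leaf_iter()
        }
        if len(species) == 1:
            max_crown = max(max_crown, a)
        else:
            min_split = min(min_split, a)
    return max_crown, min_split


def make_scenario(
    cfg: ScenarioConfig,
) -> tuple[list[BarcodeRecord], SyntheticTruth, dict[str, dendropy.Tree]]:
    """Generate a synthetic library realising the configured preset.

    Returns the records, the ground truth, and the species and gene trees
    (keys ``"species"`` and ``"gene"``).  The preset's declared property is
    checked on the realised p-distances; generation retries with spawned
    sub-seeds until it holds or the retry budget is exhausted.
    """
    cfg.validate()
    base = replace(cfg, **_PRESET_OVERRIDES.get(cfg.preset or "", {})) \
        if cfg.preset else cfg
    if cfg.preset == "singletons" and isinstance(base.n_individuals, int):
        counts = [base.n_individuals] * base.n_species
        counts[0] = 1
        base = replace(base, n_individuals=tuple(counts))
    if cfg.preset == "paraphyly" and base.n_species < 3:
        raise ScenarioError("paraphyly preset needs at least 3 species")

    ss = np.random.SeedSequence(base.seed)
    last_diag: dict = {}
    for child in ss.spawn(MAX_RETRIES):
        rng = np.random.default_rng(child)
        species_tree = simulate_species_tree(
            base.n_species, base.birth_rate, rng
        )
        try:
            gene_tree = simulate_gene_trees(
                species_tree, base.individuals(), base.coal_scale, rng
            )
        except ScenarioError:
            # species-tree terminal branch too short for the within-species
            # genealogy; draw a fresh species tree
            continue
        sep_diag: dict = {}
        if cfg.preset in ("clean_gap", "paraphyly"):
            # check tree-level separation before paying for sequence evolution
            crown, split = _crown_split_separation(gene_tree)
            sep_diag = {"max_crown_age": crown, "min_split_age": split}
            last_diag = sep_diag
            if not (math.isfinite(split)
                    and split >= SEPARATION_FACTOR * max(crown, 1e-12)):
                continue
            if (cfg.preset == "clean_gap"
                    and crown > CROWN_DEPTH_FACTOR * base.coal_scale):
                continue
        seqs = evolve_sequences(
            gene_tree, base.seq_length, base.model, base.kappa,
            base.base_freqs, rng,
        )
        species_of = {tip: tip.rsplit("_", 1)[0] if "_" in tip else tip
                      for tip in seqs}

        diagnostics: dict = {}
        if cfg.preset == "paraphyly":
            a, b = _non_sister_species_pair(species_tree)
            # merge label b into a: species a now spans two non-sister clades
            species_of = {
                tip: (a if sp == b else sp) for tip, sp in species_of.items()
            }
            diagnostics["paraphyletic_species"] = a
            diagnostics["absorbed_clade"] = b

        records = _records_from(seqs, species_of)
        max_intra, min_inter = _intra_inter(records)
        diagnostics.update(
            {"max_intra": max_intra, "min_inter": min_inter,
             "n_records": len(records)}
        )
        last_diag = diagnostics

        diagnostics.update(sep_diag)
        ok = True
        if cfg.preset == "clean_gap":
            ok = max_intra < min_inter and min_inter > 0
        elif cfg.preset == "overlapping":
            ok = _overlap_exists(records)
        elif cfg.preset == "paraphyly":
            # the merged species must have members and every other species
            # must keep a positive nearest-neighbour distance
            ok = min_inter > 0
        elif cfg.preset == "singletons":
            counts = {}
            for sp in species_of.values():
                counts[sp] = counts.get(sp, 0) + 1
            ok = any(c == 1 for c in counts.values())
        if ok:
            truth = SyntheticTruth(
                species_of=species_of,
                species_tree_newick=species_tree.as_string(schema="newick"),
                gene_tree_newick=gene_tree.as_string(schema="newick"),
                preset=cfg.preset,
                diagnostics=diagnostics,
            )
            assert is_ultrametric(gene_tree, tol=1e-6)
            return records, truth, {"species": species_tree, "gene": gene_tree}
    raise ScenarioError(
        f"preset {cfg.preset!r} not realised within {MAX_RETRIES} retries; "
        f"last diagnostics: {last_diag}"
    )
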