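"""Synthetic study generation and the packaged turtle calibration fixture.

Everything the pipeline consumes can be generated here: birth--death
chronograms, fossil-style calibrations whose minima postdate (and maxima
predate) the true divergences, and clock-like JC69 alignments.  The module
also ships the turtle (Testudines) calibration set — a fixed 23-tip
bifurcating topology with one representative tip per named clade, plus the
two eras of constraints: the *a-posteriori*-assessed minima/maxima used by
the consistency literature, and the revised *a-priori* fossil-based
minima/maxima (root: 155.6--251.4 Ma).

Every generator is bit-reproducible from (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .calibrations import Calibration
from .clock import Alignment
from .timetree import TimeTree, parse_newick

__all__ = [
    "simulate_bd_tree",
    "generate_calibrations",
    "simulate_alignment",
    "turtle_fixture",
    "turtle_table",
    "SyntheticStudy",
    "make_study",
    "make_crossval_study",
]


# ---------------------------------------------------------------------------
# birth--death tree simulation


def simulate_bd_tree(
    n_tips: int,
    birth: float,
    death: float = 0.0,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> TimeTree:
    """Complete forward birth--death simulation with ``n_tips`` survivors.

    The process starts from one lineage and runs until the standing
    diversity first reaches ``n_tips``; the present is placed at the end of
    the sojourn at ``n_tips`` lineages (the moment the next event would
    occur), so for two tips the root age is the full exponential waiting
    time at two lineages.  Extinct side branches are pruned.  Runs that die
    out restart with fresh randomness.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if not (birth > death >= 0):
        raise ValueError("require birth > death >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        tree = _one_bd_attempt(n_tips, birth, death, rng)
        if tree is not None:
            return tree
    raise RuntimeError("birth-death simulation failed to reach n_tips")


def _one_bd_attempt(n_tips, birth, death, rng):
    # node records: parent id, birth time; active = live lineage ids
    parent = [-1]
    btime = [0.0]
    active = [0]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * (birth + death)))
        i = active[int(rng.integers(k))]
        if rng.random() < birth / (birth + death):
            for _ in range(2):
                parent.append(i)
                btime.append(t)
                active.append(len(parent) - 1)
            active.remove(i)
        else:
            active.remove(i)
            if not active:
                return None
    present = t + rng.exponential(1.0 / (n_tips * (birth + death)))

    # prune to survivors, suppressing unifurcations
    children: dict[int, list[int]] = {}
    for i, p in enumerate(parent):
        children.setdefault(p, []).append(i)
    keep = set(active)

    def surviving(v):
        if v in keep:
            return True
        return any(surviving(c) for c in children.get(v, []))

    tip_name = {v: f"t{j + 1}" for j, v in enumerate(active)}

    def newick(v, stop_age):
        # age of v's split = present - btime of its children
        kids = [c for c in children.get(v, []) if surviving(c)]
        if v in keep:
            return f"{tip_name[v]}:{stop_age:.12g}"
        if len(kids) == 1:
            return newick(kids[0], stop_age)
        age = present - btime[children[v][0]]
        parts = ",".join(newick(c, age) for c in kids)
        return f"({parts}):{(stop_age - age):.12g}"

    # root of the pruned tree: walk down while only one child survives
    v = 0
    while True:
        kids = [c for c in children.get(v, []) if surviving(c)]
        if len(kids) >= 2:
            break
        v = kids[0]
    root_age = present - btime[children[v][0]]
    parts = ",".join(
        newick(c, root_age) for c in children[v] if surviving(c)
    )
    return parse_newick(f"({parts});")


# ---------------------------------------------------------------------------
# calibrations from "fossil" gaps


def _label_internal(tree: TimeTree) -> TimeTree:
    labels = list(tree.labels)
    for v in tree.internal_nodes:
        if labels[v] is None:
            labels[v] = f"n{v}"
    out = tree.with_ages(tree.ages)
    out.labels = labels
    out._label_index = {lab: i for i, lab in enumerate(labels) if lab is not None}
    return out


def generate_calibrations(
    tree: TimeTree,
    fraction_calibrated: float = 0.5,
    gap_rate: float = 0.1,
    inflation: float = 1.0,
    style: str = "min-max",
    family: str = "uniform",
    p: float = 0.1,
    c: float = 0.5,
    max_ratio: float = 1.221,
    gap_mode: str = "exponential",
    rel_gap: tuple[float, float] = (0.2, 0.7),
    seed: int = 0,
    misleading_node: str | None = None,
    misleading_factor: float = 0.5,
) -> tuple[TimeTree, list[Calibration]]:
    """Fossil-style calibrations against a tree's true node ages.

    Each selected node receives a minimum ``t_L = age - gap`` with
    ``gap ~ Exponential(rate=gap_rate)`` truncated so ``t_L > 0``; in
    ``min-max`` style it also receives ``t_U = age + excess`` with
    ``excess ~ Exponential(rate=gap_rate / inflation)``.  The root is
    always calibrated in min-max style (samplers need a bounded root).
    Minima therefore always postdate and maxima predate the truth --
    except, optionally, at ``misleading_node``, whose minimum is planted
    *above* its true age (at ``age + misleading_factor * (parent_age -
    age)``): the fixture for showing that consistency scoring can reject
    the wrong calibrations.

    ``style='min-max-linked'`` instead derives each non-root maximum from
    its own minimum as ``t_U = max_ratio * t_L`` — the construction the
    consistency literature used (its published maxima are a fixed ~1.221
    multiple of the minima).  A linked maximum inherits any error in the
    minimum, so a node with a large fossil gap gets a whole *window* that
    is young relative to the truth; the root keeps a truth-respecting
    maximum.

    ``gap_mode='relative'`` draws each gap as a uniform *fraction* of the
    node's true age (range ``rel_gap``) instead of an absolute exponential
    waiting time; this emulates clade-age-proportional fossil
    incompleteness, where deep and shallow nodes are missing comparable
    fractions of their history.

    Returns the (re-labelled) tree and the calibration list.
    """
    if not (0 < fraction_calibrated <= 1):
        raise ValueError("fraction_calibrated must lie in (0, 1]")
    if style not in ("min-only", "min-max", "min-max-linked"):
        raise ValueError(f"unknown style {style!r}")
    if tree.n_tips < 2:
        raise ValueError("degenerate tree")
    rng = np.random.default_rng(seed)
    tree = _label_internal(tree)
    nonroot = [v for v in tree.internal_nodes if v != tree.root]
    k = int(round(fraction_calibrated * len(nonroot))) if nonroot else 0
    chosen = sorted(rng.choice(len(nonroot), size=k, replace=False)) if k else []
    nodes = [tree.root] + [nonroot[i] for i in chosen]

    def trunc_exp(rate, upper):
        # exponential truncated to (0, upper), by inverse cdf
        u = rng.random()
        return -math.log1p(-u * (1.0 - math.exp(-rate * upper))) / rate

    cals = []
    for v in nodes:
        age = float(tree.ages[v])
        label = tree.node_name(v)
        if gap_mode == "relative":
            gap = age * rng.uniform(*rel_gap)
        else:
            gap = trunc_exp(gap_rate, age)
        t_L = age - gap
        if misleading_node is not None and label == misleading_node:
            par = int(tree.parent[v])
            ceiling = float(tree.ages[par]) if par != -1 else age * 1.5
            t_L = age + misleading_factor * (ceiling - age)
        minmax = style != "min-only" or v == tree.root
        if style == "min-max-linked" and v != tree.root:
            t_U = max_ratio * t_L
        elif minmax:
            t_U = age + rng.exponential(inflation / gap_rate)
            if t_U <= t_L:  # only possible for a planted bad minimum
                t_U = t_L + rng.exponential(inflation / gap_rate) + 1e-6
        else:
            t_U = None
        # min-only constraints are necessarily non-uniform (anchored on the
        # minimum); the root always keeps a bounded uniform window
        if t_U is not None and (family == "uniform" or v == tree.root):
            cals.append(Calibration(label, "uniform", t_L=t_L, t_U=t_U))
        else:
            cals.append(Calibration(label, "cauchy", t_L=t_L, p=p, c=c))
    return tree, cals


# ---------------------------------------------------------------------------
# sequence simulation


def simulate_alignment(
    tree: TimeTree, rate: float, n_sites: int, seed: int = 0
) -> Alignment:
    """JC69 simulation along the chronogram at a strict clock rate."""
    if rate < 0 or n_sites < 0:
        raise ValueError("rate and n_sites must be non-negative")
    rng = np.random.default_rng(seed)
    seqs = {tree.root: rng.integers(0, 4, size=n_sites)}
    for v in tree.preorder_internal():
        for ch in tree.children[v]:
            d = rate * (tree.ages[v] - tree.ages[ch])
            e = math.exp(-4.0 * d / 3.0)
            parent_seq = seqs[v]
            change = rng.random(n_sites) > (0.25 + 0.75 * e)
            shift = rng.integers(1, 4, size=n_sites)
            child = np.where(change, (parent_seq + shift) % 4, parent_seq)
            seqs[ch] = child
    bases = np.array(list("ACGT"))
    taxa, out = [], []
    for i, name in enumerate(tree.tip_names):
        taxa.append(name)
        out.append("".join(bases[seqs[i]]))
    return Alignment(tuple(taxa), tuple(out))


# ---------------------------------------------------------------------------
# the turtle fixture


def _data_path(name: str):
    return resources.files("chronocal.data").joinpath(name)


def turtle_table() -> pd.DataFrame:
    """The packaged turtle calibration table (both eras plus the published
    per-method consistency verdicts, carried as annotation columns)."""
    with resources.as_file(_data_path("turtle_table.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def turtle_tree() -> TimeTree:
    with resources.as_file(_data_path("turtle_tree.nwk")) as p:
        return parse_newick(p.read_text())


def turtle_fixture(era: str = "priori") -> tuple[TimeTree, list[Calibration]]:
    """The turtle chronogram plus one era of uniform soft-max calibrations.

    ``era='priori'`` returns the revised fossil-based constraints (22
    calibrated clades, root Testudines 155.6--251.4 Ma).  ``era='posteriori'``
    returns the constraint set the consistency literature assessed; the
    root keeps the fossil-based maximum (251.4 Ma) that cross-validation
    applies, rows with no usable maximum are carried in :func:`turtle_table`
    but yield no calibration here.
    """
    if era not in ("priori", "posteriori"):
        raise ValueError("era must be 'priori' or 'posteriori'")
    tree = turtle_tree()
    df = turtle_table()
    lo, hi = (
        ("min_priori", "max_priori") if era == "priori" else ("min_post", "max_post")
    )
    cals = []
    for _, row in df.iterrows():
        if not bool(row["attached"]) or pd.isna(row[lo]):
            continue
        t_U = row[hi]
        if pd.isna(t_U):
            if row["node_label"] == "Testudines":
                t_U = 251.4  # the root maximum applied in cross-validation
            else:
                continue
        cals.append(
            Calibration(str(row["node_label"]), "uniform", float(row[lo]), float(t_U))
        )
    return tree, cals


def make_crossval_study(
    n_tips: int = 10,
    birth: float = 0.02,
    rate: float = 0.002,
    n_sites: int = 800,
    base_gap: float = 0.15,
    depth_gap: float = 0.45,
    seed: int = 0,
) -> SyntheticStudy:
    """A synthetic study exercising calibration cross-validation.

    Every internal node is calibrated.  Fossil gaps are *age-proportional*:
    the minimum sits a fraction ``base_gap + depth_gap * age / root_age``
    (plus small uniform noise) below the true age, so deep clades are
    missing proportionally more of their early history — large fossil gaps
    where they matter most.  Maxima are conservative, drawn 10--40% above
    the true ages, so maxima always predate nothing.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_bd_tree(n_tips, birth, seed=seed)
    tree, _ = generate_calibrations(tree, fraction_calibrated=1.0, seed=seed)
    root_age = float(tree.ages[tree.root])
    cals = []
    for v in tree.internal_nodes:
        age = float(tree.ages[v])
        phi = base_gap + depth_gap * age / root_age + rng.uniform(-0.05, 0.05)
        cals.append(
            Calibration(
                tree.node_name(v),
                "uniform",
                t_L=age * (1.0 - phi),
                t_U=age * (1.0 + rng.uniform(0.1, 0.4)),
            )
        )
    aln = simulate_alignment(tree, rate, n_sites, seed=seed + 2)
    return SyntheticStudy(
        tree, cals, aln, birth, 0.0, math.nan, math.nan, rate, n_sites, seed
    )


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete generated input set: truth, constraints, optional data."""

    tree: TimeTree
    calibrations: list[Calibration]
    alignment: Alignment | None
    birth: float
    death: float
    gap_rate: float
    inflation: float
    rate: float | None
    n_sites: int
    seed: int


def make_study(
    n_tips: int = 8,
    birth: float = 0.02,
    death: float = 0.0,
    fraction_calibrated: float = 0.5,
    gap_rate: float = 0.1,
    inflation: float = 1.0,
    style: str = "min-max",
    rate: float | None = 0.002,
    n_sites: int = 2000,
    seed: int = 0,
    misleading_node: str | None = None,
) -> SyntheticStudy:
    """One fully reproducible synthetic study.

    Defaults emulate a vertebrate-scale problem: birth rate 0.02/lineage/Ma
    (root ages of order 10^2 Ma at 8 tips), mean fossil gap 10 Ma below the
    truth and mean maximum excess 10 Ma above it, clock rate 0.002
    substitutions/site/Ma.
    """
    tree = simulate_bd_tree(n_tips, birth, death, seed=seed)
    tree, cals = generate_calibrations(
        tree,
        fraction_calibrated=fraction_calibrated,
        gap_rate=gap_rate,
        inflation=inflation,
        style=style,
        seed=seed + 1,
        misleading_node=misleading_node,
    )
    aln = (
        simulate_alignment(tree, rate, n_sites, seed=seed + 2)
        if rate is not None and n_sites > 0
        else None
    )
    return SyntheticStudy(
        tree, cals, aln, birth, death, gap_rate, inflation, rate, n_sites, seed
    )
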