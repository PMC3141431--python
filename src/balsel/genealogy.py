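"""Haplotype genealogy: infinite-sites screening, median-joining networks,
perfect-phylogeny gene trees and TMRCA estimation.

Balancing selection leaves two or more deeply separated haplotype clades;
this module reconstructs that structure and dates the deepest split. The
gene-tree machinery assumes the infinite-sites model without
recombination, so data are first screened with the four-gamete test and
incompatible variants (and, rarely, recombinant-like haplotypes) removed.

TMRCA comes in two flavours: a fast deterministic moment estimator that
clocks the basal bipartition of the haplotype distance matrix against the
mutation rate, and a Griffiths-Tavare importance sampler on the
infinite-sites configuration that grid-maximizes the likelihood over theta
and reports the likelihood-weighted posterior mean TMRCA. Times scaled in
2 N_e units are converted to years via N_e = theta_ML / (4 mu) and the
generation time.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from balsel.diversity import diversity_summary, pairwise_ld
from balsel.regionio import MISSING, HaplotypeAlignment, OutgroupAlignment, Region


class IncompatibleSitesError(ValueError):
    """Data violate the infinite-sites assumption."""


# ---------------------------------------------------------------------------
# four-gamete screening
# ---------------------------------------------------------------------------

@dataclass
class FourGameteResult:
    """Outcome of the four-gamete screen.

    ``incompatible_pairs`` are bp-position pairs showing all four gametes in
    the original data; ``removed_sites``/``removed_haplotypes`` are the
    greedy suggestions that restore compatibility (sites first, a haplotype
    only when it alone explains >= 3 incompatibilities); ``filtered`` is the
    alignment with those removals applied.
    """

    incompatible_pairs: list[tuple[int, int]]
    removed_sites: list[int]
    removed_haplotypes: list[int]
    filtered: HaplotypeAlignment

    @property
    def compatible(self) -> bool:
        return not self.incompatible_pairs


def _incompatible_pairs(H: np.ndarray) -> list[tuple[int, int]]:
    """Column-index pairs displaying all four gametes (biallelic columns)."""
    m = H.shape[1]
    pairs = []
    for i in range(m):
        for j in range(i + 1, m):
            ok = (H[:, i] != MISSING) & (H[:, j] != MISSING)
            g = set(zip(H[ok, i].tolist(), H[ok, j].tolist()))
            if {(0, 0), (0, 1), (1, 0), (1, 1)} <= g:
                pairs.append((i, j))
    return pairs


def four_gamete_screen(aln: HaplotypeAlignment) -> FourGameteResult:
    """Detect recombination/recurrent-mutation signals and suggest removals.

    Triallelic columns are flagged for removal outright. A haplotype is
    removed (before any further site removal) when it is the sole carrier
    of the rare gamete in at least three incompatible pairs — the classic
    single-recombinant signature. Remaining incompatibilities are resolved
    greedily, dropping the site involved in the most pairs (ties to the
    lower position).
    """
    tri_cols = [j for j in range(aln.m) if aln.haplotypes[:, j].max() > 1]
    keep_cols = [j for j in range(aln.m) if j not in set(tri_cols)]
    H = aln.haplotypes[:, keep_cols]
    pairs0 = _incompatible_pairs(H)
    incompatible_bp = [(int(aln.positions[keep_cols[i]]),
                        int(aln.positions[keep_cols[j]])) for i, j in pairs0]

    # haplotype removal: sole carrier of the rare gamete in >= 3 pairs
    removed_haps: list[int] = []
    blame: Counter[int] = Counter()
    for i, j in pairs0:
        ok = (H[:, i] != MISSING) & (H[:, j] != MISSING)
        gametes = Counter(zip(H[ok, i].tolist(), H[ok, j].tolist()))
        rare = min(gametes, key=lambda g: (gametes[g], g))
        if gametes[rare] == 1:
            carrier = next(r for r in np.flatnonzero(ok)
                           if (H[r, i], H[r, j]) == rare)
            blame[int(carrier)] += 1
    rows = np.ones(aln.n, dtype=bool)
    for hap, count in blame.most_common():
        if count >= 3:
            removed_haps.append(hap)
            rows[hap] = False

    Hh = H[rows]
    pairs = _incompatible_pairs(Hh)
    removed_cols: set[int] = set()
    while pairs:
        counts: Counter[int] = Counter()
        for i, j in pairs:
            counts[i] += 1
            counts[j] += 1
        worst = min(counts, key=lambda c: (-counts[c], aln.positions[keep_cols[c]]))
        removed_cols.add(worst)
        pairs = [(i, j) for i, j in pairs if worst not in (i, j)]

    removed_sites = sorted(int(aln.positions[j]) for j in tri_cols) + sorted(
        int(aln.positions[keep_cols[c]]) for c in removed_cols)
    final_cols = [c for k, c in enumerate(keep_cols) if k not in removed_cols]
    sub = HaplotypeAlignment(
        region=aln.region,
        haplotypes=aln.haplotypes[np.ix_(rows, final_cols)],
        positions=aln.positions[final_cols],
        populations=aln.populations[rows],
        sample_ids=[s for s, k in zip(aln.sample_ids, rows) if k],
        alleles=[aln.alleles[c] for c in final_cols],
    )
    # drop columns made monomorphic by haplotype removal
    seg = [j for j in range(sub.m)
           if np.unique(sub.haplotypes[:, j][sub.haplotypes[:, j] != MISSING]).size >= 2]
    if len(seg) < sub.m:
        sub = HaplotypeAlignment(
            region=sub.region, haplotypes=sub.haplotypes[:, seg],
            positions=sub.positions[seg], populations=sub.populations,
            sample_ids=sub.sample_ids, alleles=[sub.alleles[j] for j in seg])
    return FourGameteResult(
        incompatible_pairs=incompatible_bp,
        removed_sites=removed_sites,
        removed_haplotypes=sorted(removed_haps),
        filtered=sub,
    )


# ---------------------------------------------------------------------------
# LD-guided subregion selection
# ---------------------------------------------------------------------------

def select_ld_subregion(aln: HaplotypeAlignment, min_r2: float = 0.5) -> Region:
    """Longest contiguous run of common sites with all pairwise r^2 >= min_r2.

    Common = minor allele count >= 2, biallelic. Returns the Region spanning
    the first to last site of the run (leftmost run on ties). Raises when no
    qualifying pair exists, in which case the full region should be analysed.
    """
    common = []
    for j in range(aln.m):
        col = aln.haplotypes[:, j]
        called = col[col != MISSING]
        counts = np.bincount(called.astype(int))
        if counts.size == 2 and counts.min() >= 2:
            common.append(j)
    if len(common) < 2:
        raise ValueError("fewer than 2 common biallelic sites; "
                         "analyse the full region")
    ld = pairwise_ld(aln)
    r2 = {(row.pos_i, row.pos_j): row.r2 for row in ld.itertuples()}

    def pair_ok(a: int, b: int) -> bool:
        key = (int(aln.positions[a]), int(aln.positions[b]))
        return r2.get(key, 0.0) >= min_r2

    best: tuple[int, int] | None = None
    start = 0
    for end in range(len(common)):
        while start < end and not all(
                pair_ok(common[k], common[end]) for k in range(start, end)):
            start += 1
        if end > start:
            cand = (start, end)
            if best is None or (cand[1] - cand[0]) > (best[1] - best[0]):
                best = cand
    if best is None:
        raise ValueError(f"no site pair reaches r^2 >= {min_r2}; "
                         "analyse the full region")
    lo = int(aln.positions[common[best[0]]])
    hi = int(aln.positions[common[best[1]]])
    return Region(aln.region.chrom, lo, hi + 1,
                  f"{aln.region.name}_ld" if aln.region.name else "ld_subregion")


# ---------------------------------------------------------------------------
# median-joining network
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    """Median-joining haplotype network.

    Nodes are haplotype vectors (tuples of 0/1 codes); observed nodes carry
    their frequency and population composition, inferred median vectors
    have frequency 0. Edge weights are mutational (Hamming) differences and
    each edge lists the differing variant columns.
    """

    graph: nx.Graph
    positions: np.ndarray

    @property
    def total_weight(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def observed_nodes(self) -> list[tuple]:
        return [v for v, d in self.graph.nodes(data=True) if d["observed"]]

    def median_nodes(self) -> list[tuple]:
        return [v for v, d in self.graph.nodes(data=True) if not d["observed"]]

    def to_graphml(self, path) -> None:
        g = nx.relabel_nodes(self.graph,
                             {v: "".join(map(str, v)) for v in self.graph})
        for _, d in g.nodes(data=True):
            d["populations"] = ";".join(
                f"{p}:{c}" for p, c in sorted(d.get("populations", {}).items()))
        for _, _, d in g.edges(data=True):
            d["variants"] = ";".join(str(x) for x in d["variants"])
        nx.write_graphml(g, str(path))

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tweight\tvariants\n")
            for u, v, d in self.graph.edges(data=True):
                fh.write("\t".join(["".join(map(str, u)), "".join(map(str, v)),
                                    str(d["weight"]),
                                    ";".join(map(str, d["variants"]))]) + "\n")


def _hamming(u: tuple, v: tuple) -> int:
    return sum(a != b for a, b in zip(u, v))


def _msn_edges(nodes: list[tuple], epsilon: int = 0) -> list[tuple[tuple, tuple, int]]:
    """Minimum-spanning-network links: process distances ascending, keeping
    every link between components whose separation is within ``epsilon`` of
    minimal at the step where they first become connectable."""
    import itertools

    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    pairs = sorted(((u, v, _hamming(u, v)) for u, v in itertools.combinations(nodes, 2)),
                   key=lambda t: t[2])
    edges = []
    idx = 0
    while idx < len(pairs):
        d = pairs[idx][2]
        batch = [p for p in pairs if d <= p[2] <= d + epsilon]
        added = [(u, v, dd) for u, v, dd in batch if find(u) != find(v)]
        edges.extend(added)
        for u, v, _ in added:
            parent[find(u)] = find(v)
        idx = next((k for k in range(idx, len(pairs)) if pairs[k][2] > d),
                   len(pairs))
    return edges


def median_joining_network(
    haplotypes: HaplotypeAlignment | dict[str, int],
    epsilon: int = 0,
    populations: dict[str, dict[str, int]] | None = None,
) -> HaplotypeNetwork:
    """Bandelt median-joining network of distinct haplotypes.

    Accepts an alignment (distinct rows with their frequencies and
    population composition) or a mapping from haplotype strings to counts.
    Triallelic columns are split into two binary indicator columns with a
    warning. Iterates minimum-spanning-network construction and majority
    median-vector addition to closure, then prunes obsolete medians.
    """
    if isinstance(haplotypes, HaplotypeAlignment):
        aln = haplotypes
        cols = []
        for j in range(aln.m):
            col = aln.haplotypes[:, j]
            if col.max() > 1:
                warnings.warn("triallelic site split into two binary columns "
                              "for network construction", stacklevel=2)
                cols.append((col == 1).astype(int))
                cols.append((col == 2).astype(int))
            else:
                cols.append(np.clip(col, 0, 1).astype(int))
        M = np.column_stack(cols) if cols else np.zeros((aln.n, 0), int)
        freqs: Counter[tuple] = Counter(map(tuple, M.tolist()))
        popcomp: dict[tuple, Counter] = {}
        for row, p in zip(map(tuple, M.tolist()), aln.populations):
            popcomp.setdefault(row, Counter())[p] += 1
        positions = aln.positions
    else:
        seqs = list(haplotypes)
        alphabet = [sorted({s[j] for s in seqs}) for j in range(len(seqs[0]))]
        if any(len(a) > 2 for a in alphabet):
            raise ValueError("string input must be binary per column")
        M = np.array([[alphabet[j].index(s[j]) for j in range(len(s))]
                      for s in seqs], int)
        freqs = Counter()
        for s, row in zip(seqs, map(tuple, M.tolist())):
            freqs[row] += haplotypes[s]
        popcomp = {row: Counter(populations.get(s, {})) if populations else Counter()
                   for s, row in zip(seqs, map(tuple, M.tolist()))}
        positions = np.arange(M.shape[1])

    observed = set(freqs)
    if len(observed) < 2:
        raise ValueError("need >= 2 distinct haplotypes")
    nodes: set[tuple] = set(observed)

    for _ in range(200):  # closure loop; bounded defensively
        edges = _msn_edges(sorted(nodes), epsilon)
        adj: dict[tuple, set] = {v: set() for v in nodes}
        for u, v, _d in edges:
            adj[u].add(v)
            adj[v].add(u)
        candidates: dict[tuple, int] = {}
        for u in nodes:
            for v in adj[u]:
                for w in adj[u] | adj[v]:
                    if w in (u, v):
                        continue
                    m = tuple(1 if (a + b + c) >= 2 else 0
                              for a, b, c in zip(u, v, w))
                    if m in nodes:
                        continue
                    lam = _hamming(m, u) + _hamming(m, v) + _hamming(m, w)
                    if m not in candidates or lam < candidates[m]:
                        candidates[m] = lam
        if not candidates:
            break
        lam_min = min(candidates.values())
        new = {m for m, lam in candidates.items() if lam <= lam_min + epsilon}
        nodes |= new

    # prune medians that add nothing: degree <= 1, or degree-2 on a geodesic
    while True:
        edges = _msn_edges(sorted(nodes), epsilon)
        degree: Counter[tuple] = Counter()
        neigh: dict[tuple, list] = {v: [] for v in nodes}
        for u, v, _d in edges:
            degree[u] += 1
            degree[v] += 1
            neigh[u].append(v)
            neigh[v].append(u)
        removable = None
        for v in nodes - observed:
            if degree[v] <= 1:
                removable = v
                break
            if degree[v] == 2:
                a, b = neigh[v]
                if _hamming(a, b) == _hamming(a, v) + _hamming(v, b):
                    removable = v
                    break
        if removable is None:
            break
        nodes.discard(removable)

    g = nx.Graph()
    for v in nodes:
        obs = v in observed
        g.add_node(v, observed=obs, frequency=freqs.get(v, 0),
                   populations=dict(popcomp.get(v, {})))
    for u, v, d in _msn_edges(sorted(nodes), epsilon):
        variants = [int(positions[j]) if j < len(positions) else j
                    for j in range(len(u)) if u[j] != v[j]]
        g.add_edge(u, v, weight=d, variants=variants)
    return HaplotypeNetwork(graph=g, positions=np.asarray(positions))


# ---------------------------------------------------------------------------
# perfect-phylogeny gene tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    carriers: frozenset
    mutations: list[int] = field(default_factory=list)  # bp positions
    children: list["TreeNode"] = field(default_factory=list)
    multiplicity: int = 0  # > 0 for haplotype-class leaves


@dataclass
class GeneTree:
    """Rooted perfect phylogeny with mutations placed on branches.

    The root is the ancestral (outgroup) state; leaves are haplotype
    classes with multiplicities summing to n. Each variant appears on
    exactly one branch.
    """

    root: TreeNode
    n: int

    def mutation_clades(self) -> set[frozenset]:
        """Carrier sets of all mutation-bearing branches (the
        mutation-distinguishable resolution of the genealogy)."""
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> None:
            if node.mutations:
                out.add(node.carriers)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            label = ""
            if node.multiplicity:
                label = f"x{node.multiplicity}"
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                return f"({inner}){label}:{len(node.mutations)}"
            return f"{label}:{len(node.mutations)}"

        return f"({','.join(fmt(c) for c in self.root.children)})root;"


def build_gene_tree(aln: HaplotypeAlignment,
                    og: OutgroupAlignment | None = None) -> GeneTree:
    """Unique perfect phylogeny of outgroup-polarized, compatible data.

    Sites are polarized from the attached outgroup (``og``; defaults to the
    alignment's code-0 allele for synthetic data), grouped by identical
    derived-carrier sets, and nested by subset inclusion. Raises on
    unpolarized sites or on any incompatible site pair, naming the
    offenders.
    """
    if og is not None:
        if og.alignment is not aln and og.alignment.m != aln.m:
            raise ValueError("outgroup was attached to a different alignment")
        anc = og.ancestral_code
        bad = [int(p) for p, a in zip(aln.positions, anc) if a == MISSING]
        if bad:
            raise IncompatibleSitesError(f"unpolarized sites at {bad}")
    else:
        anc = np.zeros(aln.m, dtype=np.int8)

    carriers: dict[int, frozenset] = {}
    for j in range(aln.m):
        col = aln.haplotypes[:, j]
        if col.max() > 1:
            raise IncompatibleSitesError(
                f"triallelic site at {int(aln.positions[j])}: screen first")
        derived = frozenset(np.flatnonzero((col != MISSING) & (col != anc[j])).tolist())
        if not derived or len(derived) == aln.n:
            continue
        carriers[j] = derived

    sets = sorted(set(carriers.values()), key=len, reverse=True)
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i], sets[j]
            if a & b and not (b <= a):
                pa = [int(aln.positions[k]) for k, c in carriers.items() if c == a]
                pb = [int(aln.positions[k]) for k, c in carriers.items() if c == b]
                lo, hi = sorted((pa[0], pb[0]))
                raise IncompatibleSitesError(
                    f"incompatible site pair {lo} / {hi}")

    everyone = frozenset(range(aln.n))
    root = TreeNode(carriers=everyone)
    node_of: dict[frozenset, TreeNode] = {everyone: root}
    for s in sets:  # descending size: parent already inserted
        parent = root
        while True:
            nxt = next((c for c in parent.children
                        if c.multiplicity == 0 and s <= c.carriers), None)
            if nxt is None:
                break
            parent = nxt
        node = TreeNode(carriers=s,
                        mutations=[int(aln.positions[k])
                                   for k, c in carriers.items() if c == s])
        # re-home children that are subsets of the new node
        inside = [c for c in parent.children if c.carriers <= s]
        for c in inside:
            parent.children.remove(c)
            node.children.append(c)
        parent.children.append(node)
        node_of[s] = node

    # attach haplotype-class leaves
    classes: Counter[tuple] = Counter(map(tuple, aln.haplotypes.tolist()))
    for hap, count in sorted(classes.items()):
        members = frozenset(
            i for i in range(aln.n) if tuple(aln.haplotypes[i]) == hap)
        # smallest mutation clade containing the class
        best = everyone
        for s in sets:
            if members <= s and len(s) < len(best):
                best = s
        node_of[best].children.append(
            TreeNode(carriers=members, multiplicity=count))
    return GeneTree(root=root, n=aln.n)


# ---------------------------------------------------------------------------
# TMRCA estimation
# ---------------------------------------------------------------------------

@dataclass
class TmrcaEstimate:
    """TMRCA in coalescent units and calendar years.

    ``t_scaled`` is in units of 2 N_e generations;
    ``t_years = t_scaled * 2 * N_e * generation_years``.
    """

    t_scaled: float
    theta_ml: float  # per site
    N_e: float
    t_years: float
    mu: float
    generation_years: float
    method: str
    mc_se: float | None = None
    seed: int | None = None


def _pairwise_diff_matrix(aln: HaplotypeAlignment) -> np.ndarray:
    H = aln.haplotypes
    n = aln.n
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (H[i] != MISSING) & (H[j] != MISSING)
            D[i, j] = D[j, i] = np.sum(H[i, ok] != H[j, ok])
    return D


def estimate_tmrca(
    aln: HaplotypeAlignment,
    mu: float,
    generation_years: float = 25.0,
    method: Literal["moment", "coalescent_ml"] = "moment",
    theta_per_site: float | None = None,
    n_proposals: int = 100_000,
    seed: int = 0,
) -> TmrcaEstimate:
    """Estimate the TMRCA of the sampled haplotypes.

    moment (default)
        Deepest-split moment estimator: average-linkage clustering of the
        pairwise difference matrix defines the basal bipartition; the mean
        per-site difference across that split, clocked at 2 mu per
        generation pair, dates the root. Deterministic.
    coalescent_ml
        Griffiths-Tavare importance sampling on the infinite-sites
        configuration (data must pass the four-gamete screen); theta is
        grid-maximized and the reported TMRCA is the likelihood-weighted
        mean at theta_ML, with a Monte-Carlo standard error.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    summ = diversity_summary(aln)
    if summ.S == 0:
        raise ValueError("no segregating sites: TMRCA unidentifiable")
    theta_site = theta_per_site if theta_per_site is not None else summ.theta_w
    N_e = theta_site / (4.0 * mu)

    if method == "moment":
        D = _pairwise_diff_matrix(aln)
        condensed = squareform(D, checks=False)
        link = hierarchy.linkage(condensed, method="average")
        labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
        a = labels == 1
        if a.all() or not a.any():  # degenerate clustering: deepest pair
            d_deep = D.max() / aln.L
        else:
            d_deep = float(D[np.ix_(a, ~a)].mean()) / aln.L
        t_gen = d_deep / (2.0 * mu)
        t_scaled = t_gen / (2.0 * N_e)
        return TmrcaEstimate(t_scaled=t_scaled, theta_ml=theta_site, N_e=N_e,
                             t_years=t_gen * generation_years, mu=mu,
                             generation_years=generation_years, method=method)

    if method != "coalescent_ml":
        raise ValueError(f"unknown method {method!r}")
    theta0 = theta_site * aln.L  # region-total 4 N mu L
    grid = theta0 * np.array([0.4, 0.6, 0.8, 1.0, 1.3, 1.7, 2.2])
    per_point = max(200, n_proposals // len(grid))
    rng = np.random.default_rng(seed)
    best = None
    for theta in grid:
        logw, tmrca = _gt_sample(aln, theta, per_point, rng)
        mx = logw.max()
        w = np.exp(logw - mx)
        logL = mx + math.log(w.mean())
        wm = float(np.sum(w * tmrca) / w.sum())
        var = float(np.sum(w * (tmrca - wm) ** 2) / w.sum())
        ess = float(w.sum() ** 2 / np.sum(w * w))
        se = math.sqrt(var / max(ess, 1.0))
        if best is None or logL > best[0]:
            best = (logL, theta, wm, se)
    _, theta_hat, t_scaled, se = best
    theta_site_hat = theta_hat / aln.L
    N_e = theta_site_hat / (4.0 * mu)
    if t_scaled > 0 and se > 0.1 * t_scaled:
        warnings.warn(f"Monte-Carlo SE {se:.3g} exceeds 10% of the TMRCA "
                      f"estimate {t_scaled:.3g}; increase n_proposals",
                      stacklevel=2)
    return TmrcaEstimate(
        t_scaled=t_scaled, theta_ml=theta_site_hat, N_e=N_e,
        t_years=t_scaled * 2.0 * N_e * generation_years, mu=mu,
        generation_years=generation_years, method=method, mc_se=se, seed=seed)


def _lineage_paths(aln: HaplotypeAlignment) -> list[tuple[int, ...]]:
    """Each haplotype as its root-to-tip mutation path (site column indices
    ordered by decreasing derived-carrier count, ties by position)."""
    carriers = []
    for j in range(aln.m):
        col = aln.haplotypes[:, j]
        if col.max() > 1 or np.any(col == MISSING):
            raise IncompatibleSitesError(
                "coalescent_ml needs complete biallelic data; screen first")
        carriers.append(frozenset(np.flatnonzero(col == 1).tolist()))
    order = sorted(range(aln.m), key=lambda j: (-len(carriers[j]), aln.positions[j]))
    paths = []
    for i in range(aln.n):
        path = tuple(j for j in order if i in carriers[j])
        paths.append(path)
    return paths


def _gt_sample(aln: HaplotypeAlignment, theta: float, reps: int,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Griffiths-Tavare proposal runs: returns (log-weights, TMRCAs in 2N)."""
    base = Counter(_lineage_paths(aln))
    logw = np.empty(reps)
    tmrca = np.empty(reps)
    for r in range(reps):
        state = dict(base)
        n = sum(state.values())
        lw = 0.0
        t = 0.0
        while n > 1:
            # feasible events with recursion coefficients
            events: list[tuple[str, tuple, float]] = []
            mutation_carriers: Counter[int] = Counter()
            for path, cnt in state.items():
                for site in path:
                    mutation_carriers[site] += cnt
            for path, cnt in state.items():
                if cnt >= 2:
                    events.append(("coal", path, cnt * (cnt - 1.0)))
                if cnt == 1 and path:
                    last = path[-1]
                    if mutation_carriers[last] == 1:
                        # removable: the newest mutation is private to this
                        # lineage; merging into an existing type j carries
                        # the (n_j + 1) factor of the recursion
                        parent = path[:-1]
                        factor = state.get(parent, 0) + 1.0
                        events.append(("mut", path, theta * factor))
            total = sum(w for _, _, w in events)
            if total == 0:
                lw = -np.inf
                break
            lw += math.log(total) - math.log(n * (n - 1.0 + theta))
            t += rng.exponential(2.0 / (n * (n - 1.0 + theta)))
            pick = rng.uniform(0, total)
            acc = 0.0
            for kind, path, w in events:
                acc += w
                if pick <= acc:
                    break
            if kind == "coal":
                state[path] -= 1
                n -= 1
            else:
                parent = path[:-1]
                state.pop(path)
                state[parent] = state.get(parent, 0) + 1
        logw[r] = lw
        tmrca[r] = t
    return logw, tmrca
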