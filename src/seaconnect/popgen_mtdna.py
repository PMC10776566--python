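"""Mitochondrial control-region analysis: haplotypes, diversity, F_ST, networks.

Aligned sequences are collapsed to haplotypes (H1, H2, ... in order of
discovery), summarised as per-locality count tables, compared with a
frequency-based F_ST, and related through a median-joining network in the
style of Bandelt, Forster & Röhl: iterate a minimum-spanning network over
the current node set, add majority-consensus (quasi-median) vectors of
linked triplets while they reduce network cost, and prune unused medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "HaplotypeAlignment",
    "HaplotypeTable",
    "collapse_haplotypes",
    "haplotype_diversity",
    "fst_haplotype",
    "fst_haplotype_matrix",
    "median_joining",
    "minimum_spanning_network",
    "hamming",
]

ALPHABET = set("ACGTN-")
AMBIG = set("N-")


@dataclass
class HaplotypeAlignment:
    """Equal-length nucleotide sequences with sample ids and locality labels."""

    ids: list
    localities: list
    sequences: list

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("empty alignment")
        L = len(self.sequences[0])
        for s in self.sequences:
            if len(s) != L:
                raise ValueError("sequences must all have the same length")
            if set(s) - ALPHABET:
                raise ValueError(f"illegal characters in sequence: {set(s) - ALPHABET}")
        if not (len(self.ids) == len(self.localities) == len(self.sequences)):
            raise ValueError("ids, localities and sequences must align")

    def __len__(self):
        return len(self.sequences)

    @property
    def seq_len(self) -> int:
        return len(self.sequences[0])

    def to_fasta(self, path) -> None:
        recs = [
            SeqRecord(Seq(s), id=f"{i}|{loc}", description="")
            for i, loc, s in zip(self.ids, self.localities, self.sequences)
        ]
        SeqIO.write(recs, path, "fasta")

    @classmethod
    def from_fasta(cls, path, localities: dict | None = None) -> "HaplotypeAlignment":
        ids, locs, seqs = [], [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            if "|" in rec.id:
                sid, loc = rec.id.split("|", 1)
            else:
                sid, loc = rec.id, None
            if localities is not None:
                loc = localities.get(sid, loc)
            ids.append(sid)
            locs.append(loc if loc is not None else "unknown")
            seqs.append(str(rec.seq).upper())
        return cls(ids=ids, localities=locs, sequences=seqs)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes (H1..Hk by discovery order) × per-locality counts."""

    haplotypes: dict  # label -> sequence
    counts: pd.DataFrame  # index = haplotype labels, columns = localities
    assignments: dict  # sample id -> haplotype label

    @property
    def n_samples(self) -> int:
        return int(self.counts.to_numpy().sum())

    def pooled_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def frequencies(self, locality: str | None = None) -> pd.Series:
        c = self.pooled_counts() if locality is None else self.counts[locality]
        return c / c.sum()


def hamming(a: str, b: str, skip_ambiguous: bool = True) -> int:
    """Hamming distance; N/- sites are excluded pairwise when requested."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    d = 0
    for x, y in zip(a, b):
        if skip_ambiguous and (x in AMBIG or y in AMBIG):
            continue
        if x != y:
            d += 1
    return d


def collapse_haplotypes(aln: HaplotypeAlignment, ambiguous_policy: str = "merge") -> HaplotypeTable:
    """Collapse identical sequences to haplotypes with per-locality counts.

    ``merge``: a sequence containing N/- joins the first haplotype matching
    at all its resolved sites; ``strict``: exact string identity only.
    """
    if ambiguous_policy not in ("merge", "strict"):
        raise ValueError("ambiguous_policy must be 'merge' or 'strict'")
    labels: list = []
    hap_seq: dict = {}
    assignments = {}
    pops = list(dict.fromkeys(aln.localities))
    counts: dict = {}
    for sid, loc, seq in zip(aln.ids, aln.localities, aln.sequences):
        target = None
        if ambiguous_policy == "merge" and (set(seq) & AMBIG):
            for lab in labels:
                if hamming(seq, hap_seq[lab], skip_ambiguous=True) == 0:
                    target = lab
                    break
        else:
            for lab in labels:
                if hap_seq[lab] == seq:
                    target = lab
                    break
        if target is None and ambiguous_policy == "merge" and not (set(seq) & AMBIG):
            for lab in labels:
                if hap_seq[lab] == seq:
                    target = lab
                    break
        if target is None:
            target = f"H{len(labels) + 1}"
            labels.append(target)
            hap_seq[target] = seq
        assignments[sid] = target
        counts[(target, loc)] = counts.get((target, loc), 0) + 1
    mat = pd.DataFrame(0, index=labels, columns=pops, dtype=int)
    for (lab, loc), c in counts.items():
        mat.loc[lab, loc] = c
    return HaplotypeTable(haplotypes=hap_seq, counts=mat, assignments=assignments)


def haplotype_diversity(table: HaplotypeTable, locality: str | None = None) -> float:
    """Nei's haplotype diversity h = n/(n−1) (1 − Σ p_i²); NaN when n < 2."""
    c = (table.pooled_counts() if locality is None else table.counts[locality]).to_numpy(float)
    n = c.sum()
    if n < 2:
        return np.nan
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def _gene_diversity_unbiased(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts / n
    return n / (n - 1.0) * (1.0 - np.sum(p**2))


def _fst_from_counts(ca: np.ndarray, cb: np.ndarray) -> float:
    """(H_T − H_S)/H_T from two haplotype count vectors (unbiased diversities)."""
    na, nb = ca.sum(), cb.sum()
    pa, pb = ca / na, cb / nb
    pbar = 0.5 * (pa + pb)
    n_harm = 2.0 / (1.0 / na + 1.0 / nb)
    ht_raw = 1.0 - np.sum(pbar**2)
    # Nei & Chesser small-sample corrections (haploid data, r = 2 demes)
    hs_raw = 1.0 - 0.5 * (np.sum(pa**2) + np.sum(pb**2))
    hs_c = n_harm / (n_harm - 1.0) * hs_raw
    ht_c = ht_raw + hs_c / (2.0 * n_harm)
    if ht_c <= 0:
        return 0.0
    return float((ht_c - hs_c) / ht_c)


def fst_haplotype(
    table: HaplotypeTable,
    pop_a: str,
    pop_b: str,
    n_perm: int = 1000,
    seed: int | None = None,
):
    """Frequency-based pairwise F_ST between two localities with permutation p.

    F_ST = (H_T − H_S)/H_T using small-sample-corrected gene diversities;
    identical monomorphic localities give 0 by definition. Significance by
    permuting samples between the two localities.
    """
    ca = table.counts[pop_a].to_numpy(float)
    cb = table.counts[pop_b].to_numpy(float)
    if ca.sum() == 0 or cb.sum() == 0:
        raise ValueError("both localities must be sampled")
    if (ca + cb > 0).sum() == 1:  # both fixed for the same haplotype
        return 0.0, 1.0
    fst = _fst_from_counts(ca, cb)
    if n_perm <= 0:
        return fst, np.nan
    rng = np.random.default_rng(seed)
    hap_idx = np.repeat(np.arange(len(ca)), (ca + cb).astype(int))
    na = int(ca.sum())
    count = 0
    k = len(ca)
    for _ in range(n_perm):
        perm = rng.permutation(hap_idx)
        pa = np.bincount(perm[:na], minlength=k).astype(float)
        pb = np.bincount(perm[na:], minlength=k).astype(float)
        if _fst_from_counts(pa, pb) >= fst:
            count += 1
    return fst, (1 + count) / (1 + n_perm)


def fst_haplotype_matrix(table: HaplotypeTable, n_perm: int = 1000, seed: int | None = None):
    """All pairwise haplotype-frequency F_ST values and permutation p-values."""
    from .popgen_snp import PairwiseMatrix

    pops = list(table.counts.columns)
    n = len(pops)
    vals = np.zeros((n, n))
    ps = np.zeros((n, n))
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    seeds = ss.generate_state(n * n)
    for i in range(n):
        for j in range(i + 1, n):
            f, p = fst_haplotype(table, pops[i], pops[j], n_perm=n_perm, seed=int(seeds[i * n + j]))
            vals[i, j] = vals[j, i] = f
            ps[i, j] = ps[j, i] = p
    return PairwiseMatrix(labels=pops, values=vals, pvalues=ps)


# ---------------------------------------------------------------- networks

def minimum_spanning_network(seqs: dict, epsilon: int = 0) -> nx.Graph:
    """Minimum-spanning network with tolerance ε over labelled sequences.

    Kruskal-style: scanning distances in increasing order, an edge at
    distance d joins its endpoints' clusters if the clusters were still
    separate at distance d − ε (ε=0 gives the union of all MSTs).
    """
    labels = sorted(seqs)
    d = {}
    for a, b in combinations(labels, 2):
        d[(a, b)] = hamming(seqs[a], seqs[b])
    g = nx.Graph()
    g.add_nodes_from(labels)

    def connected_using(thresh, a, b):
        par = {l: l for l in labels}

        def find(x):
            while par[x] != x:
                par[x] = par[par[x]]
                x = par[x]
            return x

        for (u, v), duv in d.items():
            if duv <= thresh:
                ru, rv = find(u), find(v)
                if ru != rv:
                    par[ru] = rv
        return find(a) == find(b)

    for (a, b), dist in sorted(d.items(), key=lambda kv: (kv[1], kv[0])):
        # include the edge unless its endpoints are already joined by
        # strictly cheaper edges (relaxed by epsilon)
        if not connected_using(dist - 1 - epsilon, a, b):
            g.add_edge(a, b, weight=dist)
    return g


def _variable_sites(seqs: dict):
    labels = sorted(seqs)
    L = len(next(iter(seqs.values())))
    sites = [i for i in range(L) if len({seqs[l][i] for l in labels}) > 1]
    return sites


def _majority_median(sa: str, sb: str, sc: str) -> str:
    out = []
    for x, y, z in zip(sa, sb, sc):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:  # three-way tie: lexicographic, deterministic
            out.append(min(x, y, z))
    return "".join(out)


def _network_cost(g: nx.Graph) -> int:
    return int(sum(d["weight"] for _, _, d in g.edges(data=True)))


def _steiner_cost(seqs: dict) -> int:
    """Weight of a minimum spanning tree over the node set (Hamming distances).

    This is the connection cost the median-joining iteration minimises:
    median vectors act as Steiner points that shorten the spanning structure,
    while the displayed network (the ε-relaxed MSN) may carry additional tied
    alternative edges.
    """
    labels = sorted(seqs)
    g = nx.Graph()
    g.add_nodes_from(labels)
    for a, b in combinations(labels, 2):
        g.add_edge(a, b, weight=hamming(seqs[a], seqs[b]))
    if g.number_of_edges() == 0:
        return 0
    return int(sum(d for _, _, d in nx.minimum_spanning_tree(g).edges(data="weight")))


def network_cost(g: nx.Graph) -> int:
    """Spanning cost of a haplotype network: MST weight over its nodes."""
    return _steiner_cost({n: d["sequence"] for n, d in g.nodes(data=True)})


def median_joining(table_or_seqs, epsilon: int = 0, max_iter: int = 20) -> nx.Graph:
    """Median-joining haplotype network.

    Accepts a :class:`HaplotypeTable` or a {label: sequence} dict. Nodes
    carry ``median=True`` for inferred intermediates; edge weights are
    Hamming mutation counts. Deterministic: candidate medians are generated
    and tie-broken in lexicographic node order.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if isinstance(table_or_seqs, HaplotypeTable):
        seqs = dict(table_or_seqs.haplotypes)
    else:
        seqs = dict(table_or_seqs)
    observed = set(seqs)
    if len(seqs) < 2:
        g = nx.Graph()
        g.add_nodes_from(seqs)
        for n in g.nodes:
            g.nodes[n]["median"] = False
        return g

    nodes = dict(seqs)
    n_median = 0
    for _ in range(max_iter):
        g = minimum_spanning_network(nodes, epsilon=epsilon)
        base_cost = _steiner_cost(nodes)
        # candidate medians from triplets linked in the current network
        candidates = []
        for b in sorted(g.nodes):
            nbrs = sorted(g.neighbors(b))
            for a, c in combinations(nbrs, 2):
                m = _majority_median(nodes[a], nodes[b], nodes[c])
                if m in nodes.values():
                    continue
                trial = dict(nodes)
                trial["__cand__"] = m
                cost = _steiner_cost(trial)
                if cost < base_cost:
                    candidates.append((cost, m))
        if not candidates:
            break
        candidates.sort(key=lambda t: (t[0], t[1]))
        n_median += 1
        nodes[f"mv{n_median}"] = candidates[0][1]  # one per sweep, deterministic
    g = minimum_spanning_network(nodes, epsilon=epsilon)
    # prune obsolete medians: unused (degree <= 1) or not shortening the network
    changed = True
    while changed:
        changed = False
        for n in sorted(g.nodes):
            if n in observed:
                continue
            without = {k: v for k, v in nodes.items() if k != n}
            if g.degree(n) <= 1 or _steiner_cost(without) <= _steiner_cost(nodes):
                nodes = without
                g = minimum_spanning_network(nodes, epsilon=epsilon)
                changed = True
    for n in g.nodes:
        g.nodes[n]["median"] = n not in observed
        g.nodes[n]["sequence"] = nodes[n]
    return g


def network_to_edgelist(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"node_a": a, "node_b": b, "mutations": d["weight"]}
        for a, b, d in sorted(g.edges(data=True))
    ]
    return pd.DataFrame(rows)
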