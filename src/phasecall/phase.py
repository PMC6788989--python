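"""Haplotype-informed genotyping.

Candidate-site allele calls from realignment are collapsed into per-read
fragments; the model assumes reads are independent and each read was drawn
from one of the two haplotypes with equal probability:

    p(R | H) = prod_r [ p(r | H1) + p(r | H2) ] / 2
    p(r | Hk) = prod over fragment sites of (1 - e) on agreement, e otherwise

where e is the allele-call error probability 10^(-q/10).  Inference
alternates (i) haplotype assembly of the current heterozygous sites by a
greedy likelihood phaser (spanning-tree majority initialization, then
hill-climbing over single-site flips and suffix switches until no move
improves p(R|H)) and (ii) full sweeps of per-site phased-genotype updates

    p(H[i] = g | R, H) = p(g) p(R | H^{i,g}) / sum_g' p(g') p(R | H^{i,g'})

over the four phased genotypes G = {0|0, 0|1, 1|0, 1|1}, until a sweep
changes nothing; the outer loop stops when the relative log-likelihood
improvement falls below delta (default 1e-5) or after max_iter (default
10) iterations.  GQ is the phred-scaled probability that the called
zygosity class (0|1 and 1|0 merged) is wrong, from the final posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .candidates import GenotypePrior

#: The four phased genotypes at a biallelic site.
PHASED_GENOTYPES: Tuple[Tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))

_MIN_ERR = 1e-10


@dataclass
class Fragment:
    """One read's allele observations restricted to candidate sites."""

    read_id: str
    sites: np.ndarray    # int site indices, strictly increasing
    alleles: np.ndarray  # 0 = ref, 1 = alt
    quals: np.ndarray    # phred allele qualities
    strand: str = "+"

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.quals = np.asarray(self.quals, dtype=float)
        if np.any(np.diff(self.sites) <= 0):
            raise ValueError("fragment site indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def error_probs(self) -> np.ndarray:
        return np.clip(10.0 ** (-self.quals / 10.0), _MIN_ERR, 0.5)


@dataclass
class HaplotypePair:
    """Current phased-genotype assignment over all candidate sites."""

    h1: np.ndarray
    h2: np.ndarray

    def __post_init__(self) -> None:
        self.h1 = np.asarray(self.h1, dtype=np.int8)
        self.h2 = np.asarray(self.h2, dtype=np.int8)
        if self.h1.shape != self.h2.shape:
            raise ValueError("haplotype length mismatch")

    @classmethod
    def from_genotypes(cls, genotypes: Sequence[Tuple[int, int]]) -> "HaplotypePair":
        h1 = np.array([g[0] for g in genotypes], dtype=np.int8)
        h2 = np.array([g[1] for g in genotypes], dtype=np.int8)
        return cls(h1, h2)

    def genotype(self, i: int) -> Tuple[int, int]:
        return int(self.h1[i]), int(self.h2[i])

    def het_sites(self) -> List[int]:
        return [int(i) for i in np.flatnonzero(self.h1 != self.h2)]

    def copy(self) -> "HaplotypePair":
        return HaplotypePair(self.h1.copy(), self.h2.copy())


@dataclass
class PhasedCall:
    """Final per-site output of the caller."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: Tuple[int, int]
    gq: float
    depth: Optional[int] = None
    phase_set: Optional[int] = None
    filters: Set[str] = field(default_factory=set)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]


def read_likelihood(fragment: Fragment, hap_alleles: np.ndarray) -> float:
    """log p(r | H_k) for one haplotype (allele vector over all sites)."""
    if len(fragment) == 0:
        return 0.0
    e = fragment.error_probs
    match = fragment.alleles == np.asarray(hap_alleles)[fragment.sites]
    return float(np.sum(np.where(match, np.log1p(-e), np.log(e))))


def data_likelihood(fragments: Sequence[Fragment], pair: HaplotypePair) -> float:
    """log p(R | H) = sum_r log[(p(r|H1) + p(r|H2)) / 2]."""
    total = 0.0
    for frag in fragments:
        l1 = read_likelihood(frag, pair.h1)
        l2 = read_likelihood(frag, pair.h2)
        total += np.logaddexp(l1, l2) - math.log(2.0)
    return float(total)


# ---------------------------------------------------------------------------
# greedy likelihood phaser (haplotype assembly of heterozygous sites)

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
            return True
        return False


def _restrict_fragments(fragments: Sequence[Fragment], het_sites: Sequence[int]):
    """Per-fragment (het-order-index, allele, error) triples."""
    order = {s: k for k, s in enumerate(het_sites)}
    out = []
    for frag in fragments:
        idx, alle, errs = [], [], []
        e = frag.error_probs
        for k in range(len(frag)):
            s = int(frag.sites[k])
            if s in order:
                idx.append(order[s])
                alle.append(int(frag.alleles[k]))
                errs.append(float(e[k]))
        if idx:
            out.append((np.array(idx), np.array(alle), np.array(errs)))
    return out


def phase_heterozygous(fragments: Sequence[Fragment], het_sites: Sequence[int]):
    """Assemble haplotypes over the heterozygous sites.

    Returns ``(phase, blocks)``: ``phase[s]`` in {0,1} gives H1's allele at
    het site ``s`` (H2 takes the complement), and ``blocks`` partitions the
    het sites into maximal co-covered groups, each phased up to a global
    flip.  At termination no single-site flip and no suffix switch within a
    block increases p(R|H).
    """
    het_sites = sorted(int(s) for s in het_sites)
    if not het_sites:
        return {}, []
    n = len(het_sites)
    restricted = _restrict_fragments(fragments, het_sites)
    # per-fragment flat lists: order indices, alleles, log(1-e), log(e)
    frags = []
    for idx, alle, errs in restricted:
        frags.append((
            [int(i) for i in idx], [int(a) for a in alle],
            [math.log1p(-e) for e in errs], [math.log(e) for e in errs]))

    # cis/trans votes between consecutively co-covered het sites
    votes: Dict[Tuple[int, int], float] = {}
    for idx, alle, _, _ in frags:
        for k in range(len(idx) - 1):
            key = (idx[k], idx[k + 1])
            votes[key] = votes.get(key, 0.0) + (1.0 if alle[k] == alle[k + 1]
                                                else -1.0)

    uf = _UnionFind(range(n))
    # maximum spanning tree by |votes|; assign relative phases along it
    edges = sorted(votes.items(), key=lambda kv: -abs(kv[1]))
    adj: Dict[int, List[Tuple[int, float]]] = {i: [] for i in range(n)}
    for (a, b), w in edges:
        if uf.union(a, b):
            adj[a].append((b, w))
            adj[b].append((a, w))
    x = [0] * n
    seen = [False] * n
    comp = [-1] * n
    n_comp = 0
    for root in range(n):
        if seen[root]:
            continue
        stack = [root]
        seen[root] = True
        comp[root] = n_comp
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    comp[v] = n_comp
                    x[v] = x[u] if w >= 0 else 1 - x[u]
                    stack.append(v)
        n_comp += 1

    blocks_idx: List[List[int]] = [[] for _ in range(n_comp)]
    for i in range(n):
        blocks_idx[comp[i]].append(i)
    for b in blocks_idx:
        b.sort()
    # position of each site within its block's order
    bpos = [0] * n
    for block in blocks_idx:
        for p, i in enumerate(block):
            bpos[i] = p

    def lse2(u, v):
        m, d = (u, v - u) if u >= v else (v, u - v)
        return m + math.log1p(math.exp(d))

    # cached log p(r|H1), log p(r|H2) over het sites
    la = [0.0] * len(frags)
    lb = [0.0] * len(frags)
    for f, (idx, alle, tm, tx) in enumerate(frags):
        l1 = l2 = 0.0
        for k in range(len(idx)):
            if alle[k] == x[idx[k]]:
                l1 += tm[k]
                l2 += tx[k]
            else:
                l1 += tx[k]
                l2 += tm[k]
        la[f], lb[f] = l1, l2

    site_frags: List[List[Tuple[int, int]]] = [[] for _ in range(n)]
    for f, (idx, _, _, _) in enumerate(frags):
        for k, i in enumerate(idx):
            site_frags[i].append((f, k))
    # fragments straddling each within-block boundary t (their delta is the
    # only nonzero term; fully-inside fragments just swap labels)
    straddle: Dict[Tuple[int, int], List[int]] = {}
    frag_span = []
    for f, (idx, _, _, _) in enumerate(frags):
        bi = comp[idx[0]]
        pmin, pmax = bpos[idx[0]], bpos[idx[-1]]
        frag_span.append((bi, pmin, pmax))
        for t in range(pmin + 1, pmax + 1):
            straddle.setdefault((bi, t), []).append(f)

    eps = 1e-12
    for _ in range(100):  # safety cap; convergence is typically fast
        improved = False
        # single-site flips
        for i in range(n):
            delta = 0.0
            ups = []
            xi = x[i]
            for f, k in site_frags[i]:
                idx, alle, tm, tx = frags[f]
                if alle[k] == xi:
                    c1, c2 = tm[k], tx[k]
                else:
                    c1, c2 = tx[k], tm[k]
                nl1 = la[f] - c1 + c2
                nl2 = lb[f] - c2 + c1
                delta += lse2(nl1, nl2) - lse2(la[f], lb[f])
                ups.append((f, nl1, nl2))
            if delta > eps:
                x[i] = 1 - xi
                for f, nl1, nl2 in ups:
                    la[f], lb[f] = nl1, nl2
                improved = True
        # suffix switches within each block
        for bi, block in enumerate(blocks_idx):
            for t in range(1, len(block)):
                delta = 0.0
                ups = []
                for f in straddle.get((bi, t), ()):
                    idx, alle, tm, tx = frags[f]
                    c1 = c2 = 0.0
                    for k in range(len(idx)):
                        if bpos[idx[k]] >= t:
                            if alle[k] == x[idx[k]]:
                                c1 += tm[k]
                                c2 += tx[k]
                            else:
                                c1 += tx[k]
                                c2 += tm[k]
                    nl1 = la[f] - c1 + c2
                    nl2 = lb[f] - c2 + c1
                    delta += lse2(nl1, nl2) - lse2(la[f], lb[f])
                    ups.append((f, nl1, nl2))
                if delta > eps:
                    for i in block[t:]:
                        x[i] = 1 - x[i]
                    for f, nl1, nl2 in ups:
                        la[f], lb[f] = nl1, nl2
                    # fragments fully inside the suffix swap haplotype labels
                    done = set(u[0] for u in ups)
                    for i in block[t:]:
                        for f, _ in site_frags[i]:
                            if f not in done:
                                done.add(f)
                                la[f], lb[f] = lb[f], la[f]
                    improved = True
        if not improved:
            break

    phase = {het_sites[i]: int(x[i]) for i in range(n)}
    blocks = [[het_sites[i] for i in b] for b in blocks_idx if b]
    blocks.sort(key=lambda b: b[0])
    return phase, blocks


# ---------------------------------------------------------------------------
# per-site phased-genotype updates

def _genotype_prior_logs(prior: GenotypePrior) -> np.ndarray:
    """log p(g) over PHASED_GENOTYPES: zygosity-class priors with the het
    mass split evenly between the two orderings."""
    p00, phet, p11 = prior.zygosity_priors()
    total = p00 + phet + p11
    return np.log(np.array([p00, phet / 2.0, phet / 2.0, p11]) / total)


def update_genotype(i: int, pair: HaplotypePair, fragments: Sequence[Fragment],
                    prior: GenotypePrior):
    """Posterior over the four phased genotypes at site ``i`` with all other
    sites fixed; returns ``(posterior, best_genotype)``.

    Fragments not covering site ``i`` cancel between numerator and
    denominator and are skipped.
    """
    prior_logs = _genotype_prior_logs(prior)
    covering = [f for f in fragments if i in f.sites]
    scores = np.array(prior_logs, dtype=float)
    for g_idx, (a1, a2) in enumerate(PHASED_GENOTYPES):
        trial = pair.copy()
        trial.h1[i], trial.h2[i] = a1, a2
        for frag in covering:
            l1 = read_likelihood(frag, trial.h1)
            l2 = read_likelihood(frag, trial.h2)
            scores[g_idx] += np.logaddexp(l1, l2) - math.log(2.0)
    post = np.exp(scores - scores.max())
    post /= post.sum()
    best = PHASED_GENOTYPES[int(np.argmax(post))]
    return post, best


def zygosity_mass(posterior: np.ndarray, genotype: Tuple[int, int]) -> float:
    """Posterior mass of the genotype's zygosity class (0|1 merged with 1|0)."""
    if genotype[0] != genotype[1]:
        return float(posterior[1] + posterior[2])
    return float(posterior[PHASED_GENOTYPES.index(genotype)])


def genotype_quality(posterior: np.ndarray, genotype: Tuple[int, int],
                     cap: float = 500.0) -> float:
    mass = zygosity_mass(posterior, genotype)
    if mass >= 1.0:
        return cap
    return min(cap, -10.0 * math.log10(1.0 - mass))


@dataclass
class PhasingResult:
    pair: HaplotypePair
    posteriors: np.ndarray          # (n_sites, 4)
    gq: np.ndarray                  # per-site genotype quality
    blocks: List[List[int]]         # het-site indices per haplotype block
    ll_trace: List[float]           # data log-likelihood after each sweep
    #: log p(H) + log p(R|H) after each sweep — the quantity the
    #: posterior-argmax updates ascend (monotone by construction; the pure
    #: data term can dip when the genotype prior overrides weak evidence)
    objective_trace: List[float]
    n_outer: int
    converged: bool

    def phase_set_of(self) -> Dict[int, int]:
        """site index -> block identifier (index of first site in block)."""
        ps = {}
        for block in self.blocks:
            for s in block:
                ps[s] = block[0]
        return ps


class _LikelihoodEngine:
    """Cached per-fragment log p(r|H1/H2) with incremental site updates."""

    def __init__(self, fragments: Sequence[Fragment], pair: HaplotypePair):
        self.frags = fragments
        self.pair = pair
        self.log_match = [np.log1p(-f.error_probs) for f in fragments]
        self.log_mis = [np.log(f.error_probs) for f in fragments]
        self.l1 = np.zeros(len(fragments))
        self.l2 = np.zeros(len(fragments))
        self.site_frags: Dict[int, List[Tuple[int, int]]] = {}
        for f, frag in enumerate(fragments):
            for k, s in enumerate(frag.sites):
                self.site_frags.setdefault(int(s), []).append((f, k))
        self.refresh()

    def refresh(self) -> None:
        for f, frag in enumerate(self.frags):
            m1 = frag.alleles == self.pair.h1[frag.sites]
            m2 = frag.alleles == self.pair.h2[frag.sites]
            self.l1[f] = np.sum(np.where(m1, self.log_match[f], self.log_mis[f]))
            self.l2[f] = np.sum(np.where(m2, self.log_match[f], self.log_mis[f]))

    def data_ll(self) -> float:
        return float(np.sum(np.logaddexp(self.l1, self.l2) - math.log(2.0)))

    def site_posterior(self, i: int, prior_logs: np.ndarray) -> np.ndarray:
        cov = self.site_frags.get(i, [])
        scores = prior_logs.copy()
        cur1, cur2 = int(self.pair.h1[i]), int(self.pair.h2[i])
        for g_idx, (a1, a2) in enumerate(PHASED_GENOTYPES):
            s = 0.0
            for f, k in cov:
                frag = self.frags[f]
                al = int(frag.alleles[k])
                t_m, t_x = self.log_match[f][k], self.log_mis[f][k]
                d1 = (t_m if al == a1 else t_x) - (t_m if al == cur1 else t_x)
                d2 = (t_m if al == a2 else t_x) - (t_m if al == cur2 else t_x)
                s += np.logaddexp(self.l1[f] + d1, self.l2[f] + d2) \
                    - np.logaddexp(self.l1[f], self.l2[f])
            scores[g_idx] += s
        post = np.exp(scores - scores.max())
        return post / post.sum()

    def set_genotype(self, i: int, genotype: Tuple[int, int]) -> None:
        cur1, cur2 = int(self.pair.h1[i]), int(self.pair.h2[i])
        a1, a2 = genotype
        for f, k in self.site_frags.get(i, []):
            frag = self.frags[f]
            al = int(frag.alleles[k])
            t_m, t_x = self.log_match[f][k], self.log_mis[f][k]
            self.l1[f] += (t_m if al == a1 else t_x) - (t_m if al == cur1 else t_x)
            self.l2[f] += (t_m if al == a2 else t_x) - (t_m if al == cur2 else t_x)
        self.pair.h1[i], self.pair.h2[i] = a1, a2


def iterate(fragments: Sequence[Fragment],
            initial_genotypes: Sequence[Tuple[int, int]],
            prior: Optional[GenotypePrior] = None,
            delta: float = 1e-5, max_iter: int = 10,
            inner_cap: int = 50) -> PhasingResult:
    """Alternate haplotype assembly and phased-genotype updates.

    Each outer iteration phases the current heterozygous set, then sweeps
    per-site genotype updates (left to right, argmax of the phased-genotype
    posterior, ties keeping the current genotype) until a sweep changes
    nothing.  The loop stops when the relative improvement of log p(R|H)
    drops below ``delta`` or after ``max_iter`` iterations.
    """
    prior = prior or GenotypePrior()
    prior_logs = _genotype_prior_logs(prior)
    n = len(initial_genotypes)
    pair = HaplotypePair.from_genotypes(initial_genotypes)
    if n == 0:
        return PhasingResult(pair, np.zeros((0, 4)), np.zeros(0), [], [], [],
                             0, True)

    engine = _LikelihoodEngine(fragments, pair)

    def log_prior() -> float:
        return float(sum(prior_logs[PHASED_GENOTYPES.index(pair.genotype(i))]
                         for i in range(n)))

    ll_trace: List[float] = []
    objective_trace: List[float] = []
    converged = False
    n_outer = 0
    for n_outer in range(1, max_iter + 1):
        ll_before = engine.data_ll()
        het = pair.het_sites()
        if het:
            phase, _ = phase_heterozygous(fragments, het)
            for s, allele in phase.items():
                engine.set_genotype(s, (allele, 1 - allele))
        for _ in range(inner_cap):
            changed = 0
            for i in range(n):
                post = engine.site_posterior(i, prior_logs)
                best = PHASED_GENOTYPES[int(np.argmax(post))]
                cur = pair.genotype(i)
                if best != cur and post[PHASED_GENOTYPES.index(best)] \
                        > post[PHASED_GENOTYPES.index(cur)]:
                    engine.set_genotype(i, best)
                    changed += 1
            ll_trace.append(engine.data_ll())
            objective_trace.append(ll_trace[-1] + log_prior())
            if changed == 0:
                break
        ll_after = engine.data_ll()
        if (ll_after - ll_before) / abs(ll_before if ll_before != 0.0 else 1.0) < delta:
            converged = True
            break

    # final phasing of the converged het set, then posteriors/GQ under the
    # final haplotype pair
    het = pair.het_sites()
    blocks: List[List[int]] = []
    if het:
        phase, blocks = phase_heterozygous(fragments, het)
        for s, allele in phase.items():
            engine.set_genotype(s, (allele, 1 - allele))
    posteriors = np.zeros((n, 4))
    gq = np.zeros(n)
    for i in range(n):
        posteriors[i] = engine.site_posterior(i, prior_logs)
        gq[i] = genotype_quality(posteriors[i], pair.genotype(i))
    return PhasingResult(pair, posteriors, gq, blocks, ll_trace,
                         objective_trace, n_outer, converged)


def write_fragments(fragments: Sequence[Fragment], path: str) -> None:
    """Text dump interoperable with haplotype-assembly tools: one line per
    fragment with the read id followed by (site, allele, qual) triples."""
    with open(path, "w") as fh:
        for frag in fragments:
            triples = " ".join(
                f"{int(s)} {int(a)} {q:.1f}"
                for s, a, q in zip(frag.sites, frag.alleles, frag.quals))
            fh.write(f"{frag.read_id} {triples}\n")


def assign_reads_to_haplotypes(fragments: Sequence[Fragment],
                               pair: HaplotypePair,
                               margin: float = math.log(100.0)) -> List[str]:
    """Label each read H1/H2 when one haplotype is ``margin`` log-units more
    likely (default log 100, i.e. posterior > 0.99 under equal priors)."""
    labels = []
    for frag in fragments:
        l1 = read_likelihood(frag, pair.h1)
        l2 = read_likelihood(frag, pair.h2)
        if l1 - l2 > margin:
            labels.append("H1")
        elif l2 - l1 > margin:
            labels.append("H2")
        else:
            labels.append("unassigned")
    return labels
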