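"""Probabilistic amplicon denoising.

Raw ribosomal-gene reads are merged, quality-filtered, dereplicated and then
clustered into "true" genotypes by an abundance-aware error model: each unique
sequence is either explained as an error cloud around a more abundant parent
(PCR substitutions propagate down the amplification tree, sequencing
substitutions do not) or retained as a new genotype.  There is no fixed
distance radius for cluster membership — the decision is a one-sided Poisson
test of the observed read count against the count expected from the parent's
abundance and the per-base error rates, so closely related genotypes (2-3
mismatches) can be separated when sequencing depth supports it.

An internal two-parent chimera check runs against the whole accepted genotype
set before any sequence is admitted as a genotype.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PHRED_OFFSET = 33


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """A single read: id, bases over {A,C,G,T,N} and per-base Phred scores."""

    id: str
    bases: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class UniqueSequence:
    """A dereplicated sequence with the number of reads that collapsed onto it."""

    bases: str
    count: int
    sample_counts: Counter = field(default_factory=Counter)


@dataclass
class Genotype:
    """An accepted "ancestor" sequence.

    ``total_count`` includes the genotype's own reads plus all reads funneled
    from unique sequences assigned to it as error variants.
    """

    bases: str
    own_count: int
    total_count: int
    children: list[str] = field(default_factory=list)
    sample_counts: Counter = field(default_factory=Counter)


@dataclass
class DenoiseParams:
    """Error model and decision rule for the denoiser.

    ``pcr_error_rate`` is per base per duplication (propagating),
    ``seq_error_rate`` per base per read (non-propagating).  ``alpha`` is the
    per-query significance level of the one-sided Poisson test for admitting
    a new genotype; the default (1e-40) is deliberately extreme, in the
    DADA2 tradition, because a deep run implicitly tests thousands of error
    variants whose counts are over-dispersed by shared PCR lineages — true
    genotypes at realistic depths have tail probabilities far smaller still.  ``method`` selects the Poisson test (default) or a UNOISE-style
    abundance-skew threshold for comparison.
    """

    pcr_error_rate: float = 1e-5
    pcr_cycles: int = 30
    seq_error_rate: float = 1e-3
    alpha: float = 1e-40
    max_parent_search_distance: int = 10
    min_count: int = 2
    min_parent_skew: float = 2.0
    method: str = "poisson"  # or "unoise"
    unoise_alpha: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.max_parent_search_distance < 1:
            raise ValueError("max_parent_search_distance must be >= 1")
        if self.method not in ("poisson", "unoise"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def effective_error_rate(self) -> float:
        """Per-base substitution rate of a sequenced read relative to its genotype.

        Sequencing contributes ``seq_error_rate`` directly; PCR contributes
        ``pcr_error_rate`` once per ancestral duplication, and under
        exponential amplification the average sampled molecule is
        ``cycles / 2`` duplications old.
        """
        return self.seq_error_rate + (self.pcr_cycles / 2.0) * self.pcr_error_rate


def hamming(a: str, b: str) -> int:
    """Substitution distance between equal-length sequences.

    Unequal lengths are compared prefix-anchored, with the length difference
    counted as terminal-gap mismatches (fixed-length amplicons make this a
    rare fallback rather than the main path).
    """
    if len(a) != len(b):
        n = min(len(a), len(b))
        return sum(x != y for x, y in zip(a[:n], b[:n])) + abs(len(a) - len(b))
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# read merging and quality filtering
# ---------------------------------------------------------------------------

def merge_pairs(
    fwd: ReadRecord,
    rev: ReadRecord,
    min_overlap: int = 20,
    max_overlap_mismatch_frac: float = 0.1,
) -> ReadRecord | None:
    """Merge a forward/reverse pair by the best ungapped overlap.

    The reverse read is reverse-complemented, every overlap length from
    ``min_overlap`` up to the shorter read is scored by identity, and the
    highest-identity overlap wins (ties go to the longer overlap).  Within the
    overlap the base with the higher Phred score is taken and the merged
    quality is the higher of the two.  Returns ``None`` (reject) when no
    overlap reaches ``1 - max_overlap_mismatch_frac`` identity.
    """
    if not fwd.bases or not rev.bases:
        raise ValueError("cannot merge empty reads")
    rc = reverse_complement(rev.bases)
    rq = rev.qualities[::-1]
    lf, lr = len(fwd), len(rc)
    best: tuple[float, int] | None = None  # (identity, overlap)
    for o in range(min_overlap, min(lf, lr) + 1):
        a = fwd.bases[lf - o:]
        b = rc[:o]
        ident = sum(x == y for x, y in zip(a, b)) / o
        if best is None or ident > best[0] or (ident == best[0] and o > best[1]):
            best = (ident, o)
    if best is None or best[0] < 1.0 - max_overlap_mismatch_frac:
        return None
    ident, o = best
    bases = list(fwd.bases[: lf - o])
    quals = list(fwd.qualities[: lf - o])
    for i in range(o):
        fb, fq = fwd.bases[lf - o + i], fwd.qualities[lf - o + i]
        rb, q2 = rc[i], rq[i]
        if fb == rb:
            bases.append(fb)
        else:
            bases.append(fb if fq >= q2 else rb)
        quals.append(max(fq, q2))
    bases.extend(rc[o:])
    quals.extend(rq[o:])
    return ReadRecord(id=fwd.id, bases="".join(bases), qualities=quals)


def expected_errors(read: ReadRecord) -> float:
    """Expected number of erroneous bases, EE = sum_b 10^(-Q_b/10)."""
    if not read.qualities:
        return 0.0
    q = np.asarray(read.qualities, dtype=float)
    return float(np.sum(10.0 ** (-q / 10.0)))


def filter_reads(reads: list[ReadRecord], max_ee: float = 0.5) -> list[ReadRecord]:
    """Keep reads whose expected error count is at most ``max_ee`` (default 0.5)."""
    return [r for r in reads if expected_errors(r) <= max_ee]


# ---------------------------------------------------------------------------
# dereplication
# ---------------------------------------------------------------------------

def dereplicate(
    reads: list[ReadRecord],
    samples: list[str] | None = None,
) -> list[UniqueSequence]:
    """Collapse exact duplicates; sort by decreasing count, then sequence.

    ``samples`` optionally gives one sample id per read so that per-sample
    counts are carried through denoising into the OTU table.
    """
    if samples is not None and len(samples) != len(reads):
        raise ValueError("samples must match reads one-to-one")
    counts: Counter = Counter(r.bases for r in reads)
    per_sample: dict[str, Counter] = {s: Counter() for s in counts}
    if samples is not None:
        for r, s in zip(reads, samples):
            per_sample[r.bases][s] += 1
    uniques = [
        UniqueSequence(bases=b, count=c, sample_counts=per_sample[b])
        for b, c in counts.items()
    ]
    uniques.sort(key=lambda u: (-u.count, u.bases))
    return uniques


def remove_singletons(
    uniques: list[UniqueSequence], min_count: int = 2
) -> tuple[list[UniqueSequence], int]:
    """Drop uniques below ``min_count`` reads; returns (kept, reads removed)."""
    kept = [u for u in uniques if u.count >= min_count]
    removed = sum(u.count for u in uniques if u.count < min_count)
    return kept, removed


# ---------------------------------------------------------------------------
# parent-child error model
# ---------------------------------------------------------------------------

def child_probability(
    parent: UniqueSequence | Genotype,
    child_bases: str,
    params: DenoiseParams,
) -> float:
    """Expected read count mu of ``child_bases`` as an error cloud of ``parent``.

    A read copied from the parent carries the child's d specific substitutions
    with probability p = (eps_eff/3)^d; mu = parent count x p.
    """
    count = parent.total_count if isinstance(parent, Genotype) else parent.count
    d = hamming(parent.bases, child_bases)
    if d == 0:
        raise ValueError("child is identical to parent (d = 0)")
    if d > params.max_parent_search_distance:
        raise ValueError(f"d = {d} exceeds max_parent_search_distance")
    p = (params.effective_error_rate / 3.0) ** d
    return count * p


def _tail_probability(observed: int, mu: float) -> float:
    """P(X >= observed) for X ~ Poisson(mu)."""
    if mu <= 0.0:
        return 0.0 if observed > 0 else 1.0
    return float(stats.poisson.sf(observed - 1, mu))


def chimera_check(
    query: UniqueSequence,
    accepted: list[Genotype],
    min_parent_skew: float = 2.0,
) -> tuple[bool, int | None, int | None, int | None]:
    """Two-parent single-breakpoint chimera test against accepted genotypes.

    The query is chimeric iff some breakpoint 0 < b < L and two distinct
    genotypes A, B — each at least ``min_parent_skew`` times more abundant
    than the query — satisfy query[:b] == A[:b] and query[b:] == B[b:], while
    the query equals neither parent overall.  Returns
    (is_chimera, left index, right index, breakpoint).
    """
    L = len(query.bases)
    eligible = [
        (i, g)
        for i, g in enumerate(accepted)
        if g.total_count >= min_parent_skew * query.count and len(g.bases) == L
    ]
    if len(eligible) < 2:
        return False, None, None, None
    prefix: dict[int, int] = {}
    suffix: dict[int, int] = {}
    for i, g in eligible:
        n = 0
        while n < L and query.bases[n] == g.bases[n]:
            n += 1
        prefix[i] = n
        m = 0
        while m < L and query.bases[L - 1 - m] == g.bases[L - 1 - m]:
            m += 1
        suffix[i] = m
    for i, a in eligible:
        if query.bases == a.bases:
            continue
        for j, b in eligible:
            if i == j or query.bases == b.bases:
                continue
            # need breakpoint with 0 < bp < L, bp <= prefix[i], L - bp <= suffix[j]
            lo = max(1, L - suffix[j])
            hi = min(prefix[i], L - 1)
            if lo <= hi:
                return True, i, j, lo
    return False, None, None, None


# ---------------------------------------------------------------------------
# denoising proper
# ---------------------------------------------------------------------------

def denoise(
    uniques: list[UniqueSequence],
    params: DenoiseParams | None = None,
) -> tuple[list[Genotype], dict[str, dict]]:
    """Assign unique sequences to genotypes, most abundant first.

    The most abundant sequence is always a genotype.  Each subsequent query is
    compared against all previously accepted genotypes within the search
    radius; the most likely parent is the one with the largest upper-tail
    probability P(X >= query count | Poisson(mu)).  The query becomes a new
    genotype only if that probability is below ``alpha`` for every candidate
    (its count is too high to be an error cloud), and only if it passes the
    internal chimera check; otherwise its reads funnel into the best parent's
    total count.  Funneling is transitive: counts accumulate on the ultimate
    ancestor because parents are always accepted genotypes.

    Returns the genotype list and an assignment map
    ``sequence -> {status, parent, distance, p_value}`` with status one of
    ``genotype | merged | chimera``.
    """
    params = params or DenoiseParams()
    order = sorted(uniques, key=lambda u: (-u.count, u.bases))
    genotypes: list[Genotype] = []
    assignment: dict[str, dict] = {}
    for query in order:
        candidates: list[tuple[float, float, int, int]] = []  # (pval, mu, d, idx)
        for idx, g in enumerate(genotypes):
            d = hamming(g.bases, query.bases)
            if 1 <= d <= params.max_parent_search_distance:
                mu = g.total_count * (params.effective_error_rate / 3.0) ** d
                if params.method == "unoise":
                    beta = 1.0 / 2 ** (params.unoise_alpha * d + 1)
                    pval = 1.0 if query.count <= beta * g.total_count else 0.0
                else:
                    pval = _tail_probability(query.count, mu)
                candidates.append((pval, mu, d, idx))
        best = max(candidates, default=None, key=lambda t: (t[0], -t[2], -t[3]))
        if best is not None and best[0] >= params.alpha:
            pval, mu, d, idx = best
            parent = genotypes[idx]
            parent.total_count += query.count
            parent.children.append(query.bases)
            parent.sample_counts.update(query.sample_counts)
            assignment[query.bases] = {
                "status": "merged",
                "parent": parent.bases,
                "distance": d,
                "p_value": pval,
            }
            continue
        is_chim, li, ri, bp = chimera_check(query, genotypes, params.min_parent_skew)
        if is_chim:
            assignment[query.bases] = {
                "status": "chimera",
                "parent": None,
                "distance": None,
                "p_value": None,
                "left_parent": genotypes[li].bases,
                "right_parent": genotypes[ri].bases,
                "breakpoint": bp,
                "count": query.count,
            }
            continue
        genotypes.append(
            Genotype(
                bases=query.bases,
                own_count=query.count,
                total_count=query.count,
                sample_counts=Counter(query.sample_counts),
            )
        )
        assignment[query.bases] = {
            "status": "genotype",
            "parent": None,
            "distance": None,
            "p_value": None if best is None else best[0],
        }
    return genotypes, assignment


def denoise_reads(
    reads: list[ReadRecord],
    params: DenoiseParams | None = None,
    samples: list[str] | None = None,
) -> tuple[list[Genotype], dict[str, dict], dict[str, int]]:
    """Full post-merge pipeline: dereplicate, drop singletons, denoise.

    Returns (genotypes, assignment map, stage counts).  The stage counts
    satisfy the conservation identity: total genotype reads + chimera reads +
    removed singleton reads = dereplicated read total.
    """
    params = params or DenoiseParams()
    uniques = dereplicate(reads, samples=samples)
    derep_reads = sum(u.count for u in uniques)
    kept, singleton_reads = remove_singletons(uniques, params.min_count)
    genotypes, assignment = denoise(kept, params)
    chimera_reads = sum(
        rec["count"] for rec in assignment.values() if rec["status"] == "chimera"
    )
    counts = {
        "reads_in": len(reads),
        "unique_sequences": len(uniques),
        "dereplicated_reads": derep_reads,
        "singleton_reads_removed": singleton_reads,
        "chimera_reads_discarded": chimera_reads,
        "genotypes": len(genotypes),
        "genotype_reads": sum(g.total_count for g in genotypes),
    }
    assert (
        counts["genotype_reads"] + chimera_reads + singleton_reads == derep_reads
    ), "read-count conservation violated"
    return genotypes, assignment, counts
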