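"""Independent brute-force oracles used only by the test suite.

Each oracle is a deliberately naive implementation sharing no code with
the package internals it checks.
"""

from __future__ import annotations

import math
from itertools import product


def mendelian_consistent_bruteforce(gt_f: str, gt_m: str, gt_o: str) -> bool:
    """Enumerate all four allele transmissions directly from genotype strings."""
    fa = [int(x) for x in gt_f.split("/")]
    ma = [int(x) for x in gt_m.split("/")]
    oa = sorted(int(x) for x in gt_o.split("/"))
    return any(sorted([a, b]) == oa for a in fa for b in ma)


def trio_posterior_bruteforce(ll_f, ll_m, ll_c, p: float, mu: float):
    """27-configuration trio posterior by direct enumeration.

    Returns (posterior dict keyed by (gf, gm, gc) indices, dnm_probability).
    Genotype index equals alt-allele dosage; likelihoods are logs.
    """
    genotypes = [(0, 0), (0, 1), (1, 1)]
    hw = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
    shift = max(ll_f) + max(ll_m) + max(ll_c)  # numeric stabilizer only
    joint = {}
    for i, j, k in product(range(3), repeat=3):
        target = sorted(genotypes[k])
        p_child = 0.0
        for fa in genotypes[i]:
            for ma in genotypes[j]:
                for a_out, pa in ((fa, 1 - mu), (1 - fa, mu)):
                    for b_out, pb in ((ma, 1 - mu), (1 - ma, mu)):
                        if sorted([a_out, b_out]) == target:
                            p_child += 0.25 * pa * pb
        joint[(i, j, k)] = (
            hw[i] * hw[j] * p_child * math.exp(ll_f[i] + ll_m[j] + ll_c[k] - shift)
        )
    total = sum(joint.values())
    post = {key: v / total for key, v in joint.items()}
    gt_str = ["0/0", "0/1", "1/1"]
    dnm = sum(
        v
        for (i, j, k), v in post.items()
        if not mendelian_consistent_bruteforce(gt_str[i], gt_str[j], gt_str[k])
    )
    return post, dnm


def genotype_loglik_per_read_bruteforce(
    ref_count: int, alt_count: int, other_count: int, eps: float
):
    """Per-read likelihood products for 0/0, 0/1, 1/1 (logs taken at the end)."""
    out = []
    for gt in ((0, 0), (0, 1), (1, 1)):
        log_l = 0.0
        for _ in range(ref_count):
            per_allele = [(1 - eps) if a == 0 else eps / 3 for a in gt]
            log_l += math.log(sum(per_allele) / 2)
        for _ in range(alt_count):
            per_allele = [(1 - eps) if a == 1 else eps / 3 for a in gt]
            log_l += math.log(sum(per_allele) / 2)
        for _ in range(other_count):
            log_l += math.log(eps / 3)
        out.append(log_l)
    return tuple(out)


def f1_sweep_bruteforce(scores, is_match, n_truth: int, higher_is_better: bool):
    """Best F1 over every possible inclusive cut, by direct counting.

    Candidate cuts are each observed score plus a pass-nothing sentinel;
    ties prefer the cut keeping fewest calls. Duplicate truth matches are
    impossible by table key uniqueness, so TP = passing matches.
    """
    best_f1 = -1.0
    best_cut = None
    candidate_cuts = sorted(set(scores))
    for cut in candidate_cuts:
        if higher_is_better:
            passing = [m for s, m in zip(scores, is_match) if s >= cut]
        else:
            passing = [m for s, m in zip(scores, is_match) if s <= cut]
        tp = sum(passing)
        fp = len(passing) - tp
        fn = n_truth - tp
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        n_pass = len(passing)
        if f1 > best_f1 or (f1 == best_f1 and n_pass < best_n_pass):
            best_f1, best_cut, best_n_pass = f1, cut, n_pass
    return best_f1, best_cut


def concordance_bruteforce(tables: dict[str, set]) -> dict[frozenset, int]:
    """Per-key membership tally over every non-empty caller subset."""
    from itertools import combinations

    union = set().union(*tables.values())
    counts = {}
    names = sorted(tables)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts[frozenset(combo)] = 0
    for key in union:
        members = frozenset(n for n in names if key in tables[n])
        counts[members] += 1
    return counts
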