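"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, kept separate from the package so the
checks stay independent of the code paths they verify.
"""

from __future__ import annotations

TOL = 1e-9


def brute_force_dominance(triples):
    """Dominance labels by exhaustive pairwise and mixture comparison.

    An option is *dominated* when another option attains at least its
    effect at no more cost (one inequality strict). A remaining option is
    *weakly dominated* when a convex mixture of two other remaining
    options matches its effect at strictly lower cost.
    """
    labels = {}
    for name_k, cost_k, eff_k in triples:
        dominated = any(
            (cost_j <= cost_k + TOL and eff_j >= eff_k - TOL)
            and (cost_j < cost_k - TOL or eff_j > eff_k + TOL)
            for name_j, cost_j, eff_j in triples
            if name_j != name_k
        )
        labels[name_k] = "dominated" if dominated else "undominated"

    survivors = [t for t in triples if labels[t[0]] == "undominated"]
    for name_k, cost_k, eff_k in survivors:
        others = [t for t in survivors if t[0] != name_k]
        for _, cost_i, eff_i in others:
            for _, cost_j, eff_j in others:
                if not eff_i < eff_k < eff_j:
                    continue
                lam = (eff_k - eff_i) / (eff_j - eff_i)
                mix_cost = (1 - lam) * cost_i + lam * cost_j
                if mix_cost < cost_k - TOL:
                    labels[name_k] = "weakly_dominated"
    return labels
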