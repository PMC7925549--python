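"""Independent brute-force recomputation of the Global Tree Difference.

Deliberately shares no code with the package: cumulative counts come from
naive recursion over a raw parent map, the cosine uses the plain
dot-over-norms formula, and every region is processed in an explicit loop.
"""

import numpy as np


def brute_force_gtd(parents: dict, direct_a: dict, direct_b: dict) -> float:
    ids = sorted(parents)
    children = {i: sorted(j for j in ids if parents[j] == i) for i in ids}
    root = next(i for i in ids if parents[i] is None)

    def cum(direct, r):
        return direct.get(r, 0) + sum(cum(direct, c) for c in children[r])

    total_a = cum(direct_a, root)
    total_b = cum(direct_b, root)
    numerator = 0.0
    denominator = 0.0
    for r in ids:
        has_direct = direct_a.get(r, 0) > 0 or direct_b.get(r, 0) > 0
        if len(children[r]) + (1 if has_direct else 0) < 2:
            continue
        u = [cum(direct_a, c) for c in children[r]]
        v = [cum(direct_b, c) for c in children[r]]
        if has_direct:
            u.append(direct_a.get(r, 0))
            v.append(direct_b.get(r, 0))
        u = np.array(u, dtype=float)
        v = np.array(v, dtype=float)
        if not u.any() or not v.any():
            continue
        m = (cum(direct_a, r) / total_a + cum(direct_b, r) / total_b) / 2.0
        d = 1.0 - float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        numerator += m * d
        denominator += m
    return numerator / denominator
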