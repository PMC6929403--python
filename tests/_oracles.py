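"""Independent brute-force recomputations used to check the scoring path.

Everything here iterates sample-by-sample and pair-by-pair in plain Python,
deliberately sharing no code with the vectorized implementation.
"""

import math


def brute_support(binary_rows, lnc, mirna, mr, samples):
    """binary_rows: dict rna -> dict sample -> 0/1."""
    count = 0
    for s in samples:
        triple = (binary_rows[lnc][s], binary_rows[mirna][s], binary_rows[mr][s])
        if triple == (0, 1, 0) or triple == (1, 0, 1):
            count += 1
    return count


def brute_score_network(binary_rows, lnc_ids, mirna, mr_ids, samples, log_base="e"):
    """Returns dict (lnc, mr) -> (supp, p_joint, p_lnc, p_mr, pmi-or-None)."""
    supp = {
        (l, m): brute_support(binary_rows, l, mirna, m, samples)
        for l in lnc_ids
        for m in mr_ids
    }
    total = sum(supp.values())
    if total == 0:
        raise ValueError("no competition samples")
    out = {}
    for l in lnc_ids:
        for m in mr_ids:
            p_joint = supp[(l, m)] / total
            p_lnc = sum(supp[(l, m2)] for m2 in mr_ids) / total
            p_mr = sum(supp[(l2, m)] for l2 in lnc_ids) / total
            if p_joint == 0:
                score = None
            else:
                score = math.log(p_joint / (p_lnc * p_mr))
                if log_base == "2":
                    score /= math.log(2.0)
            out[(l, m)] = (supp[(l, m)], p_joint, p_lnc, p_mr, score)
    return out


def random_binary_instance(rng, max_lnc=3, max_mr=3, max_samples=8):
    """A random tiny network instance: ids, sample list, binary rows."""
    n = int(rng.integers(1, max_lnc + 1))
    m = int(rng.integers(1, max_mr + 1))
    s = int(rng.integers(2, max_samples + 1))
    samples = [f"s{i}" for i in range(s)]
    lnc_ids = [f"lnc{i}" for i in range(n)]
    mr_ids = [f"mr{i}" for i in range(m)]
    rows = {}
    for rna in lnc_ids + ["mir"] + mr_ids:
        bits = rng.integers(0, 2, size=s)
        rows[rna] = {smp: int(b) for smp, b in zip(samples, bits)}
    return lnc_ids, "mir", mr_ids, samples, rows
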