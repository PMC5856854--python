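"""Independent brute-force evaluator of the pose-scoring scheme.

Deliberately written as plain element-by-element loops, sharing no code
with padif.scorer, so the two implementations check each other.
"""


def brute_force_score(median_values, weights, pose_values):
    """Return (R, P, overlap, O_max, O_real, O_rel, sum_S, S_tot)."""
    n_atoms = len(median_values)
    n_terms = len(median_values[0])
    ref_elements = [(m, n) for m in range(n_atoms) for n in range(n_terms)
                    if median_values[m][n] < 0]
    pose_elements = [(m, n) for m in range(n_atoms) for n in range(n_terms)
                     if pose_values[m][n] < 0]
    R = len(ref_elements)
    if R == 0:
        raise ValueError("R = 0")
    P = len(pose_elements)
    o_max = P / R
    if o_max > 1:
        o_max = 1.0
    sum_s = 0.0
    overlap = 0
    for (m, n) in ref_elements:
        v = pose_values[m][n]
        if v < 0:
            sum_s += weights[m][n]
            overlap += 1
        elif v > 0:
            sum_s -= weights[m][n]
    o_real = overlap / R
    o_rel = o_real / o_max if o_max > 0 else 0.0
    s_tot = sum_s - (1.0 - o_rel) * abs(sum_s)
    return R, P, overlap, o_max, o_real, o_rel, sum_s, s_tot
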