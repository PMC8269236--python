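"""Independent brute-force oracles used by the test suite.

The alignment oracle enumerates all monotone matchings between two sequences.
Under affine gap costs, the optimal alignment restricted to a fixed matching
places each inter-match run of unmatched residues in a single gap per side, so
maximising over matchings equals maximising over alignments — without any
dynamic programming shared with the implementation under test.
"""

import itertools


def gap_cost(k, gap_open, gap_extend):
    return 0.0 if k == 0 else gap_open + k * gap_extend


def enumerate_alignment_scores(a, b, scheme):
    """(global score, local score) by exhaustive monotone-matching enumeration."""
    sub = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend

    def gap(k):
        return gap_cost(k, go, ge)

    n, m = len(a), len(b)
    best_global = -(gap(n) + gap(m))  # the all-gap alignment
    best_local = 0.0                  # the empty local alignment
    for k in range(1, min(n, m) + 1):
        for qs in itertools.combinations(range(n), k):
            for rs in itertools.combinations(range(m), k):
                subs = sum(float(sub[a[i], b[j]]) for i, j in zip(qs, rs))
                internal = sum(
                    gap(qs[t] - qs[t - 1] - 1) + gap(rs[t] - rs[t - 1] - 1)
                    for t in range(1, k)
                )
                best_local = max(best_local, subs - internal)
                ends = (
                    gap(qs[0])
                    + gap(rs[0])
                    + gap(n - 1 - qs[-1])
                    + gap(m - 1 - rs[-1])
                )
                best_global = max(best_global, subs - internal - ends)
    return best_global, best_local


def argmax_best_hit(query, refs, config, scheme):
    """Exhaustive best-hit oracle: align against every reference, apply the
    thresholds, take the top score, break ties by identity then ref id."""
    from cobpath.align import align_global, align_local

    align = align_global if config.mode == "global" else align_local
    candidates = []
    for ref_id, seq in refs.items():
        aln = align(query, seq, scheme)
        if aln.score >= config.resolved_min_score and aln.identity >= config.min_identity:
            candidates.append((-aln.score, -aln.identity, ref_id))
    if not candidates:
        return None
    candidates.sort()
    return candidates[0][2]
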