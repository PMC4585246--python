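"""Independent brute-force application of the first-pass reading rules.

Works directly from the definitions, word by word, without any of the
run-scanning machinery of the production parser.  Used as the oracle in
the exhaustive-equivalence tests.
"""

import math


def brute_force_word_measures(word_seq, durations, n_words):
    """``word_seq[i]`` is fixation i's word; ``durations[i]`` its length.

    Returns a list of dicts, one per word, with the literal rule
    applications spelled out.
    """
    out = []
    n = len(word_seq)
    for w in range(n_words):
        visits = [i for i in range(n) if word_seq[i] == w]
        later_before = {
            i: any(word_seq[j] > w for j in range(i)) for i in range(n)
        }
        # first pass: consecutive fixations on w from the first visit,
        # but only if nothing beyond w was fixated earlier
        first_pass = []
        if visits and not later_before[visits[0]]:
            i = visits[0]
            while i < n and word_seq[i] == w:
                first_pass.append(i)
                i += 1
        skipped = len(first_pass) == 0
        ffd = durations[first_pass[0]] if first_pass else math.nan
        gd = sum(durations[i] for i in first_pass) if first_pass else math.nan
        sfd = ffd if len(first_pass) == 1 else math.nan
        tvt = sum(durations[i] for i in visits)
        refixated = len(first_pass) >= 2
        regression_out = False
        if first_pass:
            after = first_pass[-1] + 1
            regression_out = after < n and word_seq[after] < w
        regression_in = any(later_before[i] for i in visits)
        out.append(
            dict(
                word_index=w,
                ffd=ffd,
                sfd=sfd,
                gd=gd,
                tvt=tvt,
                skipped_first_pass=skipped,
                refixated=refixated,
                regression_out=regression_out,
                regression_in=regression_in,
                first_pass=first_pass,
            )
        )
    return out
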