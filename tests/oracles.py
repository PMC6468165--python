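"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity from its verbal definition with
naive scans, sharing no code with the package internals.
"""

import math


def landmark_oracle(u, pre_U, full_U):
    """Editing landmarks by literal reading of the glossary definitions.

    ESS: the final (5'-most) editing site, moving 3'->5', that matches the
    canonical fully edited sequence with every site 3' of it also
    matching.  JSS: the first site, moving 3'->5', that does not match.
    JES: the 5'-most site with any editing action (difference from the
    pre-edited sequence).  JL: number of sites between JSS and JES.
    Sites are 1-based, 1 = 3'-most; index i-1 of the vectors is site i.
    """
    m = len(u)
    if list(u) == list(pre_U):
        eclass = "pre_edited"
    elif list(u) == list(full_U):
        eclass = "fully_edited"
    else:
        eclass = "partially_edited"
    ess = 0
    for k in range(1, m + 1):
        if all(u[i - 1] == full_U[i - 1] for i in range(1, k + 1)):
            ess = k
    jes = 0
    for k in range(1, m + 1):
        if u[k - 1] != pre_U[k - 1]:
            jes = k
    jss = ess + 1
    jl = max(0, jes - ess)
    return eclass, ess, jss, jes, jl


def tukey_threshold_oracle(values):
    """Q3 + 1.5*IQR via a hand-rolled sorted/interpolated quartile."""
    xs = sorted(float(v) for v in values)
    n = len(xs)

    def quartile(q):
        pos = q * (n - 1)
        lo = math.floor(pos)
        frac = pos - lo
        if lo + 1 < n:
            return xs[lo] * (1 - frac) + xs[lo + 1] * frac
        return xs[lo]

    q1, q3 = quartile(0.25), quartile(0.75)
    return q3 + 1.5 * (q3 - q1)


def gap_count_oracle(scan):
    """Number of editing sites in a scan string = gaps between non-T bases."""
    nonT = [i for i, b in enumerate(scan) if b != "T"]
    return len(nonT) - 1
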