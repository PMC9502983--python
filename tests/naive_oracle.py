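"""Deliberately naive re-implementation of the response rules for cross-checks.

Written independently of the package internals: plain Python arithmetic,
manual linear-interpolation quantiles, one explicit if/elif chain.
"""


def naive_quantile(values, q):
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = int(h)
    if lo == len(xs) - 1:
        return xs[lo]
    return xs[lo] + (xs[lo + 1] - xs[lo]) * (h - lo)


def naive_classify(enhancers, fold_increase_min=1.5, reduction_min=0.33,
                   constant_max_change=0.10, eps=0.5):
    """enhancers: list of (unstim, stim, overlaps) -> list of category strings."""
    pool = [(u, s) for u, s, ov in enhancers if ov]
    q25_u = naive_quantile([u for u, _ in pool], 0.25)
    q25_s = naive_quantile([s for _, s in pool], 0.25)
    q75_u = naive_quantile([u for u, _ in pool], 0.75)
    q75_s = naive_quantile([s for _, s in pool], 0.75)
    labels = []
    for u, s, ov in enhancers:
        denom = u if u > eps else eps
        if not ov:
            labels.append("no_response")
        elif s / denom >= fold_increase_min and s > q25_s:
            labels.append("increasing")
        elif 1 - s / denom >= reduction_min and u > q25_u:
            labels.append("decreasing")
        elif u >= q75_u and s >= q75_s and abs(s - u) / denom <= constant_max_change:
            labels.append("constant")
        else:
            labels.append("unclassified")
    return labels
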