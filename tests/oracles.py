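"""Independent brute-force reference implementations used to oracle-test
the package's numerics.  Everything here is written from the definitions,
deliberately avoiding the library code paths (no scipy.stats, no pandas
ranking, no vectorized shortcuts shared with the implementation)."""

from __future__ import annotations

import math


def naive_percentiles(values):
    """Hazen percentiles with midranks, straight from the definition:
    rank r of x = (# strictly below) + (# equal + 1) / 2, percentile =
    100 * (r - 0.5) / n.  Missing values (NaN) stay missing and are not
    counted in n."""
    present = [v for v in values if not math.isnan(v)]
    n = len(present)
    out = []
    for v in values:
        if math.isnan(v):
            out.append(float("nan"))
            continue
        below = sum(1 for u in present if u < v)
        equal = sum(1 for u in present if u == v)
        r = below + (equal + 1) / 2.0
        out.append(100.0 * (r - 0.5) / n)
    return out


def naive_ks_statistic(a, b):
    """Two-sample Kolmogorov-Smirnov statistic: the maximum absolute
    difference between the two empirical CDFs, evaluated at every sample
    point."""
    a = sorted(a)
    b = sorted(b)
    best = 0.0
    for x in a + b:
        fa = sum(1 for u in a if u <= x) / len(a)
        fb = sum(1 for u in b if u <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best


def naive_rmse(y, y_hat):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(y, y_hat)) / len(y))


def naive_pearson(y, y_hat):
    n = len(y)
    my = sum(y) / n
    mh = sum(y_hat) / n
    num = sum((a - my) * (b - mh) for a, b in zip(y, y_hat))
    da = math.sqrt(sum((a - my) ** 2 for a in y))
    db = math.sqrt(sum((b - mh) ** 2 for b in y_hat))
    return num / (da * db)


def naive_mae_without_patient_bias(y, y_hat, patient_ids):
    """Mean |error - patient mean error| from the definition, with an
    explicit per-patient pass."""
    errors = [b - a for a, b in zip(y, y_hat)]
    bias = {}
    for p in set(patient_ids):
        es = [e for e, q in zip(errors, patient_ids) if q == p]
        bias[p] = sum(es) / len(es)
    return sum(abs(e - bias[p]) for e, p in zip(errors, patient_ids)) / len(errors)
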