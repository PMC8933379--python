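"""Independent closed-form oracle for the complete 2x2 crossover.

Classical ANOVA estimator: the treatment effect is half the difference
between sequences of the mean within-subject period differences. Kept free
of any abspk.crossover code so it can cross-check the mixed-model fit.
"""
import math

import numpy as np
from scipy import stats


def closed_form_crossover(observations, alpha=0.10):
    """Returns dict(ratio, lo, hi, gm_test, gm_reference, sigma_within, df).

    Requires complete data: every subject observed in both periods.
    """
    per = {(o.subject_id, o.period): o for o in observations}
    subjects = sorted({o.subject_id for o in observations})
    sequences = sorted({o.sequence for o in observations})
    assert len(sequences) == 2

    diffs = {s: [] for s in sequences}
    by_treatment_sequence = {}
    for sid in subjects:
        o1, o2 = per[(sid, 1)], per[(sid, 2)]
        diffs[o1.sequence].append(o2.ln_value - o1.ln_value)
        for o in (o1, o2):
            by_treatment_sequence.setdefault((o.treatment, o.sequence), []).append(
                o.ln_value)

    # sequence in which the test treatment falls in period 2
    def test_in_period2(seq):
        sid = next(s for s in subjects if per[(s, 1)].sequence == seq)
        return per[(sid, 2)].treatment == "test"

    seq_a = next(s for s in sequences if test_in_period2(s))
    seq_b = next(s for s in sequences if not test_in_period2(s))
    d_a = np.asarray(diffs[seq_a])
    d_b = np.asarray(diffs[seq_b])
    tau = (d_a.mean() - d_b.mean()) / 2.0
    n1, n2 = len(d_a), len(d_b)
    df = n1 + n2 - 2
    pooled = (((d_a - d_a.mean()) ** 2).sum()
              + ((d_b - d_b.mean()) ** 2).sum()) / df
    se = math.sqrt(pooled * (1.0 / n1 + 1.0 / n2)) / 2.0
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)

    adj = {}
    for trt in ("test", "reference"):
        adj[trt] = np.mean([
            np.mean(by_treatment_sequence[(trt, s)]) for s in sequences
        ])
    return dict(
        ratio=100.0 * math.exp(tau),
        lo=100.0 * math.exp(tau - t_crit * se),
        hi=100.0 * math.exp(tau + t_crit * se),
        gm_test=math.exp(adj["test"]),
        gm_reference=math.exp(adj["reference"]),
        sigma_within=math.sqrt(pooled / 2.0),
        df=df,
    )
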