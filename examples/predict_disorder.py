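"""Calibrate the disorder-probability curve and score held-out predictions.

Generates annotated synthetic proteins whose disordered labels follow a
known probability law over smoothed ADM plot counts, fits the calibration
curve on a training split, predicts on a held-out split at the default
threshold (0.62), and reports ACCp/ACCw plus the swept optimum.
"""

import numpy as np

import admap

table = admap.make_table("two-class", seed=11)
train = admap.make_annotated_set(40, seed=11, table=table)
held_out = admap.make_annotated_set(15, seed=211, table=table)

curve = admap.calibrate(train, table)

entries = []
pooled = admap.ConfusionCounts()
for record, annotation in held_out:
    pred = admap.predict(record.residues, table, curve, theta=0.62)
    entries.append((pred.probability, annotation))
    pooled = pooled + admap.confusion(pred, annotation)

sweep = admap.threshold_sweep(entries, np.round(np.arange(0.05, 0.96, 0.01), 2))

print(f"training proteins : {len(train)}  held-out: {len(held_out)}")
print(f"curve domain      : counts {curve.domain[0]:.0f}..{curve.domain[1]:.0f}")
print(f"ACCp @ 0.62       : {admap.acc_p(pooled):.3f}")
print(f"ACCw @ 0.62       : {admap.acc_w(pooled):.3f}")
print(f"best ACCw         : {sweep.acc_w.max():.3f} at theta {sweep.best_theta_accw}")
# ACCw balances sensitivity on disordered residues against specificity on
# ordered ones, so it is the measure to tune the threshold on when chains
# are only partially disordered.
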