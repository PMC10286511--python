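"""Fitting the switch model to published adrenergic / angiotensin assays.

Loads the packaged assay table (maximal G-alpha and beta-arrestin responses
and log EC50s for 20 ligands), fits the three-parameter stepwise model to
each ligand, classifies bias, and shows that every trajectory endpoint sits
on a corner of the bias plot — the common-saturation prediction.
"""

import math

from bois import bias

for receptor in bias.RECEPTORS:
    records = bias.load_assay_fixture(receptor)
    print(f"\n{receptor} receptor ({len(records)} ligands):")
    for rec in records:
        label = bias.classify_ligand(rec, threshold=0.5)
        try:
            fit = bias.fit_bois(rec, r_t=2.5)
            first = fit.first_pathway
            pred = (f", predicted 2nd logEC50 = {math.log10(fit.ec50_second_pred):.2f}"
                    if fit.ec50_second_pred else "")
            detail = f"first switch {first} at logEC50 {fit.log_ec50_first:.2f}{pred}"
        except bias.InactiveLigandError:
            detail = "no activation measured"
        traj = bias.trajectory_for_record(rec)
        print(f"  {rec.ligand:10s} {label:15s} endpoint {traj.endpoint}  ({detail})")
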