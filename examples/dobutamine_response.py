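"""Dobutamine dose response in the presence of VVC and APC collaterals.

Dobutamine raises end-systolic elastance (and coronary oxygen demand, hence
coronary flow) at each dose on the calibrated 0/5/10 ug/kg/min grid.  In
the collateral-laden Fontan circulation this raises cardiac output and
venous saturation but *de*saturates arterial blood: the larger desaturated
coronary and collateral admixture outweighs the flow gain.
"""

import pandas as pd

import fontansim as fs

rows = {}
for dose in (0.0, 5.0, 10.0):
    cfg = fs.ScenarioConfig(vvc_enabled=True, apc_enabled=True,
                            dobutamine_dose=dose)
    r = fs.run_scenario(cfg)
    rows[f"{dose:.0f} ug/kg/min"] = {
        "SaO2 (%)": round(r.oxygen.sao2, 1),
        "SvO2 (%)": round(r.oxygen.svo2, 1),
        "CO (L/min)": round(r.mean.co, 2),
        "net CO (L/min)": round(r.mean.net_co, 2),
        "Ees/Ea": round(r.indices.ees_over_ea, 2),
        "EF (%)": round(r.indices.ef, 1),
    }

print(pd.DataFrame(rows).T.to_string())
print("\nHigher dose: CO and SvO2 rise while SaO2 falls; net CO barely moves -")
print("the extra output recirculates through collaterals and the dilated")
print("coronary bed instead of perfusing tissue.")
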