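"""Run the no-collateral Fontan baseline and print its operating point.

Builds the calibrated closed-loop TCPC model (fenestration open, no
collaterals), integrates to the periodic steady state, and solves the
oxygen mass balance.  Saturations are percent, outputs L/min, pressures
mmHg: SaO2 ~96% reflects the small fenestration/coronary venous admixture
below the 98% pulmonary end-capillary saturation, and SvO2 ~62% is fixed by
the Fick balance at a resting VO2I of 125 mL/min/m2.
"""

import fontansim as fs

result = fs.run_scenario(fs.ScenarioConfig())

print("Fontan baseline (no collaterals, fenestration open)")
print(f"  SaO2            {result.oxygen.sao2:6.1f} %")
print(f"  SvO2            {result.oxygen.svo2:6.1f} %")
print(f"  cardiac output  {result.mean.co:6.2f} L/min")
print(f"  net CO (caval)  {result.mean.net_co:6.2f} L/min")
print(f"  mean AoP        {result.mean.node_pressures['aorta']:6.1f} mmHg")
print(f"  Fontan pressure {result.mean.node_pressures['conduit']:6.1f} mmHg")
print(f"  EF              {result.indices.ef:6.1f} %")
print(f"  Ees/Ea          {result.indices.ees_over_ea:6.2f}")
print(f"  SW/PVA          {result.indices.sw_over_pva:6.2f}")
print(f"  beats to converge: {result.convergence['beats']}")
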