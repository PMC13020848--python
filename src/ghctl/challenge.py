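"""Published benchmark tables from the 2nd International Autonomous
Greenhouse Challenge comparison.

These small constant tables are inputs to the deviation-ratio benchmark: the
cumulative resource usage of the five challenge teams plus the manually
operated reference compartment, alongside the reinforcement-learning agent,
and the normalized average crop-yield parameters per team.
"""

from __future__ import annotations

import pandas as pd

AGENT_KEY = "Our RL Agent"

RESOURCE_PARAMETERS = ["CO2", "Elec high", "Elec low", "Heat", "Irrigation"]

#: Cumulative resource usage over the full production episode, per strategy.
TEAM_RESOURCE_USAGE = pd.DataFrame(
    {
        "CO2":        [56.20, 56.15, 56.45, 55.84, 56.11, 56.04, 55.09],
        "Elec high":  [76.05, 76.02, 75.70, 75.44, 76.79, 75.82, 76.45],
        "Elec low":   [88.26, 87.84, 87.87, 87.83, 89.22, 88.07, 89.58],
        "Heat":       [48.95, 48.95, 48.66, 48.56, 48.93, 48.63, 49.56],
        "Irrigation": [10.96, 10.90, 11.01, 11.13, 10.52, 11.13, 8.31],
    },
    index=pd.Index(["AICU", "Automatoes", "Digilog", "IUACAAS",
                    "Reference", "TheAutomators", AGENT_KEY],
                   name="Team"),
)

#: Normalized average crop-yield parameters per strategy (full episode).
TEAM_CROP_YIELD = pd.DataFrame(
    {
        "Stem elongation":   [0.73, 0.75, 0.76, 0.75, 0.71, 0.69, 0.79],
        "Stem thickness":    [0.70, 0.73, 0.75, 0.74, 0.69, 0.72, 0.73],
        "Cumulative trusses": [0.26, 0.27, 0.28, 0.30, 0.24, 0.21, 0.42],
    },
    index=pd.Index(["AICU", "Automatoes", "Digilog", "IUACAAS",
                    "Reference", "TheAutomators", AGENT_KEY],
                   name="Team"),
)
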