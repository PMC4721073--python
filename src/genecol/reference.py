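"""Published variance-component estimates for the two study species.

These are the printed percent-scale variance components (with standard
errors in parentheses in the original tables) from the common-garden
study of interior spruce (*Picea glauca* x *engelmannii*) and lodgepole
pine (*Pinus contorta*) that this package models.  They serve as worked
inputs for the V_pop formula and as magnitude templates for the
synthetic generator; they are data, not values this package estimates.

Components are on the percent-of-total scale; because V_pop is a ratio
of components, percent and absolute scales give identical V_pop.
"""

from __future__ import annotations

import pandas as pd

TERMS = ["population", "environment", "pop_env", "block", "location", "residual"]
TRAITS = ["height", "diameter", "budbreak", "budset", "cold_injury"]

#: Percent variance components for interior spruce (rows: model terms).
SPRUCE_COMPONENTS = pd.DataFrame(
    {
        "height": [9.3, 35.9, 3.9, 3.1, 1.4, 46.4],
        "diameter": [11.7, 13.1, 3.9, 4.0, 2.3, 65.1],
        "budbreak": [0.5, 93.3, 0.2, 0.2, 0.1, 5.6],
        "budset": [14.8, 17.2, 5.4, 0.6, 0.0, 62.0],
        "cold_injury": [36.6, 0.3, 4.5, 2.4, 3.9, 52.3],
    },
    index=TERMS,
)

#: Standard errors of the spruce components, same layout.
SPRUCE_COMPONENT_SES = pd.DataFrame(
    {
        "height": [1.3, 29.7, 1.2, 1.1, 0.7, 1.6],
        "diameter": [1.8, 11.2, 1.8, 1.4, 1.1, 2.4],
        "budbreak": [0.1, 76.2, 0.1, 0.1, 0.1, 0.2],
        "budset": [2.1, 14.2, 1.9, 0.5, 0.2, 2.4],
        "cold_injury": [4.1, 0.9, 2.1, 1.3, 2.0, 2.3],
    },
    index=TERMS,
)

#: Published V_pop (%) for spruce, with SEs.
SPRUCE_VPOP = pd.Series(
    {"height": 16.6, "diameter": 15.2, "budbreak": 7.4, "budset": 19.3, "cold_injury": 41.1}
)
SPRUCE_VPOP_SES = pd.Series(
    {"height": 2.4, "diameter": 2.4, "budbreak": 1.7, "budset": 2.8, "cold_injury": 4.8}
)

#: Percent variance components for lodgepole pine.
PINE_COMPONENTS = pd.DataFrame(
    {
        "height": [11.7, 28.1, 2.0, 1.5, 6.5, 50.1],
        "diameter": [4.2, 19.3, 0.0, 0.8, 2.3, 73.4],
        "budbreak": [0.6, 93.9, 0.3, 0.1, 0.0, 5.1],
        "budset": [21.3, 1.9, 0.0, 0.2, 0.2, 76.4],
        "cold_injury": [12.0, 12.5, 0.0, 5.5, 2.5, 67.6],
    },
    index=TERMS,
)

#: Standard errors of the pine components.
PINE_COMPONENT_SES = pd.DataFrame(
    {
        "height": [1.6, 23.2, 1.4, 0.6, 2.6, 1.8],
        "diameter": [1.0, 15.9, 0.0, 0.5, 1.1, 2.1],
        "budbreak": [0.1, 76.7, 0.1, 0.0, 0.0, 0.2],
        "budset": [2.7, 1.6, 2.1, 0.4, 0.3, 2.9],
        "cold_injury": [1.9, 11.3, 0.0, 2.3, 1.5, 2.3],
    },
    index=TERMS,
)

#: Published V_pop (%) for pine, with SEs.
PINE_VPOP = pd.Series(
    {"height": 19.0, "diameter": 5.4, "budbreak": 10.9, "budset": 21.8, "cold_injury": 15.0}
)
PINE_VPOP_SES = pd.Series(
    {"height": 2.6, "diameter": 1.3, "budbreak": 2.1, "budset": 2.8, "cold_injury": 2.4}
)

COMPONENTS = {"spruce": SPRUCE_COMPONENTS, "pine": PINE_COMPONENTS}
COMPONENT_SES = {"spruce": SPRUCE_COMPONENT_SES, "pine": PINE_COMPONENT_SES}
VPOP = {"spruce": SPRUCE_VPOP, "pine": PINE_VPOP}
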