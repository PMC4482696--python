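"""Published San Francisco Bay Area vegetation area table.

Percent of the study region covered by each of the 22 vegetation types of
the Upland Habitat Goals vegetation map (single-grassland classification),
as printed in the source study's summary table.  These observed regional
frequencies drive the frequency-based baselines: random assignment in
proportion to frequency is correct with probability sum(f^2), and always
assigning the most common type (grassland) is correct with probability
max(f).
"""

from __future__ import annotations

import numpy as np

__all__ = ["SFBA_VEGETATION_AREA_PERCENT", "sfba_frequencies"]

#: % of study-region area per vegetation type (22 types; grassland dominant)
SFBA_VEGETATION_AREA_PERCENT = {
    "Grassland": 35.9,
    "Chamise Chaparral": 3.24,
    "Mixed Chaparral": 0.52,
    "Mixed Montane Chaparral": 5.30,
    "Coastal Scrub": 3.58,
    "Semi-Desert Scrub": 1.59,
    "Valley Oak Forest / Woodland": 0.24,
    "Blue Oak Forest / Woodland": 6.62,
    "Blue Oak-Foothill Pine Woodland": 1.12,
    "Oregon Oak Woodland": 1.31,
    "Black Oak Forest / Woodland": 0.14,
    "Coast Live Oak Forest / Woodland": 8.27,
    "Interior Live Oak Forest / Woodland": 0.31,
    "Canyon Live Oak Forest": 0.25,
    "California Bay Forest": 1.69,
    "Tanoak Forest": 0.97,
    "Montane Hardwoods": 11.3,
    "Douglas Fir Forest": 5.89,
    "Bishop Pine Forest": 0.25,
    "Knobcone Pine Forest": 0.45,
    "Ponderosa Pine Forest": 0.40,
    "Redwood Forest": 10.6,
}


def sfba_frequencies() -> tuple[list[str], np.ndarray]:
    """Class names and normalized relative frequencies of the 22 types."""
    names = list(SFBA_VEGETATION_AREA_PERCENT)
    f = np.array([SFBA_VEGETATION_AREA_PERCENT[n] for n in names], dtype=float)
    return names, f / f.sum()
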