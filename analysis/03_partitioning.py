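#!/usr/bin/env python
"""Pyruvate partitioning: the accumulation ratio across the pH range of
a glucose-fed yeast culture and the implied intracellular concentrations
for the simulated group II culture. Writes results/analysis/partitioning.csv."""

from pathlib import Path

import pandas as pd

from cytoferm import io
from cytoferm.partitioning import (
    PYRUVATE_MW,
    WeakAcidParams,
    accumulation_ratio,
    intracellular_mm,
    round_to_1sf,
)

SIMULATED = Path("results/analysis/simulated")
OUT = Path("results/analysis")


def main() -> None:
    course = pd.read_csv(SIMULATED / "timecourse_groupII.csv", comment="#")
    pyr_gl = float(course["pyruvate_gl"].iloc[-1])

    rows = []
    for state, ph_in in (("glucose-starved", 6.0), ("glucose-growth", 7.0)):
        params = WeakAcidParams(pka=2.5, ph_in=ph_in, ph_out=5.0, mw=PYRUVATE_MW)
        ratio = accumulation_ratio(params)
        inside = intracellular_mm(pyr_gl, params, unit="g/L")
        rows.append(
            {
                "state": state,
                "ph_in": ph_in,
                "accumulation_ratio": ratio,
                "accumulation_ratio_1sf": round_to_1sf(ratio),
                "extracellular_gl": pyr_gl,
                "intracellular_mm": inside,
            }
        )
        print(
            f"{state} (pH_in {ph_in}): ratio {ratio:.1f} "
            f"(~{round_to_1sf(ratio):.0f}), {pyr_gl:.3f} g/L outside "
            f"-> {inside:.1f} mM inside"
        )
    io.write_table(pd.DataFrame(rows), OUT / "partitioning.csv")


if __name__ == "__main__":
    main()
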