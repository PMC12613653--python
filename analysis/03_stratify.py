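"""Classify regions into environment types and development stages.

Environment type I/II/III from population-weighted elevation (< 300 m,
300-950 m, > 950 m; time-invariant per region) and development stage
1/2/3 from the urbanization rate (< 30%, 30-70%, > 70%; per year). Also
derives data-driven elevation classes with the exact natural-breaks
classifier as a cross-check on the fixed cut points.
"""

from pathlib import Path

import pandas as pd

from geotree_le.panel import read_panel
from geotree_le.stratify import assign_strata, jenks_breaks

OUT = Path("results")


def main() -> None:
    panel = read_panel(OUT / "panel.csv")
    expo = pd.read_csv(OUT / "exposure.csv", index_col="region")

    strata = assign_strata(panel, expo["wdem"], mode="fixed")
    strata.to_csv(OUT / "strata.csv", index=False)

    tab = strata.pivot_table(index="year", columns="stage", values="region",
                             aggfunc="count").fillna(0).astype(int)
    print("regions per development stage by year:")
    print(tab.to_string())

    breaks = jenks_breaks(expo["wdem"].to_numpy(), 3)
    print(f"natural-breaks elevation cuts on this world: "
          f"{breaks[0]:.0f} m and {breaks[1]:.0f} m "
          f"(fixed rules use 300 and 950 m)")


if __name__ == "__main__":
    main()
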