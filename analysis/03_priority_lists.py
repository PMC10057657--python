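#!/usr/bin/env python
"""Build the three priority views from the filtered DE tables.

Top-10 up/down per contrast (ranked by fold-change magnitude) and the
miRNAs changing in the same direction in both contrasts. Writes
results/priority/.
"""

from pathlib import Path

import pandas as pd

from mirtriage import io as mio
from mirtriage.prioritize import priority_table, same_direction, top_k

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    filtered = {
        c: pd.read_csv(
            ROOT / "de" / f"de_{c}_filtered.tsv",
            sep="\t", comment="#", float_precision="round_trip",
        )
        for c in ("TvN", "F1vT")
    }
    out = ROOT / "priority"
    out.mkdir(parents=True, exist_ok=True)
    for c, table in filtered.items():
        for direction in ("up", "down"):
            view = top_k(table, 10, direction)
            mio.write_frame(view, out / f"top10_{direction}_{c}.tsv")
            if len(view):
                lead = view.iloc[0]
                print(
                    f"{c} top {direction}: {lead.feature_id} "
                    f"(FC {lead.fold_change:+.2f}), {len(view)} rows"
                )
    both = same_direction(filtered["TvN"], filtered["F1vT"])
    mio.write_frame(both, out / "same_direction.tsv")
    print(f"same direction in both contrasts: {len(both)} miRNAs")
    universe = priority_table(filtered["TvN"], filtered["F1vT"], k=10)
    mio.write_frame(universe, out / "priority.tsv")
    print(f"priority universe for integration: {len(universe)} rows -> {out}")


if __name__ == "__main__":
    main()
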