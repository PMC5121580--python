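#!/usr/bin/env python
"""Report the significant m/z markers of the best validated model.

Reads the marker table and canonical-root class means written by
04_validate.py (running that stage first if needed) and prints the m/z
signals flagged significant on each canonical root, with their weights.
The planted glycerol signals (93.049, 110.058, 185.063) should appear on
the glycerol-separating root and the castor-oil signals (281.248, 299.259,
316.285) on the root contrasting untreated with castor-oil-treated
parchment.
"""
import runpy
from pathlib import Path

import pandas as pd

RUN_DIR = Path("results/04_validation")


def main() -> None:
    if not (RUN_DIR / "markers.tsv").exists():
        runpy.run_path("analysis/04_validate.py", run_name="__main__")
    markers = pd.read_csv(RUN_DIR / "markers.tsv", sep="\t")
    roots = pd.read_csv(RUN_DIR / "root_class_means.tsv", sep="\t", index_col=0)
    print("canonical-root class means:")
    print(roots.round(3).to_string())
    for j in (1, 2):
        sig = markers[markers[f"flag_root{j}"]].copy()
        sig = sig.reindex(sig[f"weight_root{j}"].abs().sort_values(ascending=False).index)
        print(f"\nsignificant markers on root {j} "
              f"(|weight| > {markers[f'threshold_root{j}'].iloc[0]}):")
        print(
            sig[["mz", f"weight_root{j}"]]
            .round({"mz": 3, f"weight_root{j}": 4})
            .to_string(index=False)
        )
    out = RUN_DIR / "significant_markers.tsv"
    markers[markers.flag_root1 | markers.flag_root2].to_csv(out, sep="\t", index=False)
    print("\nfiltered marker table written to", out)


if __name__ == "__main__":
    main()
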