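#!/usr/bin/env python
"""Per-position flexibility profiles (Neq, RMSF, bands) for each system.

Reads the per-system PB frequency and RMSF tables written by
01_simulate_ensembles.py, computes the Neq conformational-entropy profile,
attaches region annotation and qualitative flexibility bands, and writes
one flexibility table per system plus a per-region Neq summary.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import pbflex as pf

RESULTS = Path(__file__).resolve().parent.parent / "results"
IN = RESULTS / "synthetic"
OUT = RESULTS / "flexibility"

REGIONS = pf.RegionMap.default_vhh()


def load_profile(path: Path) -> pf.PBFrequencyProfile:
    df = pd.read_csv(path, sep="\t").set_index("position")
    observed = df.pop("observed_frames").to_numpy()
    freqs = df[list(pf.PB_LABELS)].to_numpy(float)
    counts = np.nan_to_num(freqs) * observed[:, None]
    return pf.PBFrequencyProfile(
        list(df.index), np.round(counts).astype(np.int64), observed
    )


def load_rmsf(path: Path) -> pf.RmsfVector:
    df = pd.read_csv(path, sep="\t")
    return pf.RmsfVector(df["rmsf"].to_numpy(), list(df["position"]))


def main() -> None:
    with open(IN / "manifest.json") as fh:
        manifest = json.load(fh)
    OUT.mkdir(parents=True, exist_ok=True)

    summary_rows = []
    for system, meta in manifest["systems"].items():
        prof = load_profile(IN / meta["pb_frequencies"])
        rv = load_rmsf(IN / meta["rmsf"])
        flex = pf.build_flexibility_profile(system, prof, rv, REGIONS)
        df = flex.to_frame()
        tag = system.replace("-", "_")
        df.to_csv(OUT / f"{tag}.flexibility.tsv", sep="\t", index=False,
                  float_format="%.6g")

        for region, grp in df.groupby("region", sort=False):
            if np.all(np.isnan(grp["neq"])):
                continue
            summary_rows.append({
                "system": system,
                "region": region,
                "max_neq": np.nanmax(grp["neq"]),
                "max_rmsf": np.nanmax(grp["rmsf"]),
            })
        cdr1 = df[df["region"] == "CDR1"]
        print(f"{system}: CDR1 max Neq {np.nanmax(cdr1['neq']):.2f} "
              f"({pf.flexibility_band(np.nanmax(cdr1['neq']))}), "
              f"CDR1 max RMSF {np.nanmax(cdr1['rmsf']):.2f} A")

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(OUT / "region_summary.tsv", sep="\t", index=False,
                   float_format="%.4g")
    print(f"wrote flexibility tables and region summary to {OUT}")


if __name__ == "__main__":
    main()
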