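#!/usr/bin/env python
"""Compare the three transit-time methods on the simulated cohorts.

Reads the tidy per-subject results from 01_simulate_cohorts.py, summarizes
PWV per method (mean ± SD), and computes Bland–Altman agreement of maximum
upslope and time-to-peak against time-to-foot with automatic baseline
correction — the method-comparison layout of the underlying study.

Writes results/method_summary.csv and results/method_agreement.csv.
"""

from pathlib import Path

import pandas as pd

import pwvkit as pk

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows_summary, rows_agreement = [], []
    for profile in ("neonate", "adolescent"):
        results = pd.read_csv(RESULTS / f"cohort_{profile}" / "results.csv")
        summary = pk.summarize_methods(results)
        summary.insert(0, "profile", profile)
        rows_summary.append(summary)

        ref = results[(results["method"] == "TTF")
                      & (results["baseline"] == "automatic")].set_index("subject_id")
        for method in ("max_upslope", "TTP"):
            other = results[results["method"] == method].set_index("subject_id")
            common = ref.index.intersection(other.index)
            bland, _ = pk.bland_altman(other.loc[common, "pwv_m_per_s"],
                                       ref.loc[common, "pwv_m_per_s"])
            rows_agreement.append({
                "profile": profile, "method": method, "reference": "TTF+automatic",
                "bias_m_per_s": bland.bias, "sd_m_per_s": bland.sd,
                "loa_low": bland.loa_low, "loa_high": bland.loa_high, "n": bland.n,
            })
            print(f"{profile:10s} {method:12s} vs TTF: "
                  f"{bland.bias:+.2f} ± {bland.sd:.2f} m/s "
                  f"(LoA {bland.loa_low:.2f} to {bland.loa_high:.2f})")

    pd.concat(rows_summary, ignore_index=True).to_csv(
        RESULTS / "method_summary.csv", index=False)
    pd.DataFrame(rows_agreement).to_csv(RESULTS / "method_agreement.csv", index=False)


if __name__ == "__main__":
    main()
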