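#!/usr/bin/env python
"""Cross-host comparison: does a good SP in one host stay good in another?

Pairs per-SP relative cutinase activities between the two hosts (repeated
isolates collapsed by mean), reports Pearson and Spearman coefficients and
concordance classes, and draws the scatter plot.  Discordant SPs — strong in
one host, weak in the other — are listed explicitly; their existence is the
practical argument for re-screening a signal-peptide library whenever the
expression host changes.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from secscreen.crosshost import concordance_classes, correlation, pair_hosts
from secscreen.io import HOST_BS, HOST_CG, campaign_sp_records, write_csv_atomic
from secscreen.phenotype import normalize_by_max


def main() -> None:
    cg = normalize_by_max(campaign_sp_records(HOST_CG))
    bs = normalize_by_max(campaign_sp_records(HOST_BS))
    pairs, only_cg, only_bs = pair_hosts(cg, bs)
    labelled, counts = concordance_classes(pairs)
    summary = correlation(labelled)

    frame = pd.DataFrame(
        {
            "sp_id": [p.sp_id for p in labelled],
            "rel_C_glutamicum_pct": [round(p.rel_host_a, 1) for p in labelled],
            "rel_B_subtilis_pct": [round(p.rel_host_b, 1) for p in labelled],
            "concordance_class": [p.concordance_class for p in labelled],
        }
    )
    write_csv_atomic(frame, "results/crosshost_pairs.csv")

    print(f"Paired {summary.n_pairs} SPs across hosts "
          f"(unmatched: {len(only_cg)} vs {len(only_bs)}).")
    print(f"Pearson r = {summary.pearson_r:.3f}, Spearman rho = {summary.spearman_rho:.3f}")
    print(f"Concordance classes: {counts}")
    disc = frame[frame["concordance_class"].str.startswith("discordant")]
    print("Discordant SPs (strong in one host only):")
    for _, r in disc.iterrows():
        print(f"  {r['sp_id']}: C. glutamicum {r['rel_C_glutamicum_pct']}% "
              f"vs B. subtilis {r['rel_B_subtilis_pct']}%")

    fig, ax = plt.subplots(figsize=(4.8, 4.8))
    colors = {
        "concordant_high": "tab:green",
        "concordant_low": "tab:gray",
        "discordant_a_high": "tab:red",
        "discordant_b_high": "tab:orange",
    }
    for cls, grp in frame.groupby("concordance_class"):
        ax.scatter(grp["rel_C_glutamicum_pct"], grp["rel_B_subtilis_pct"],
                   s=22, label=cls, color=colors[cls])
    ax.set_xlabel("relative activity, C. glutamicum [%]")
    ax.set_ylabel("relative activity, B. subtilis [%]")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig("results/crosshost_scatter.png", dpi=150)
    print("Wrote results/crosshost_pairs.csv and results/crosshost_scatter.png")


if __name__ == "__main__":
    main()
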