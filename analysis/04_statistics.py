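#!/usr/bin/env python
"""Cross-condition statistics from the tables written by 01–03.

Reads results/docking_success.tsv, results/volume_subsamples.tsv and
results/contact_occupancy.tsv and computes:

- a binomial p-value for the open vs. occluded docking success counts
  (upper tail of the open count under the occluded empirical rate, with the
  1/(2n) floor when the occluded count is zero);
- an equal-variance two-tailed t-test on the triplicate large-volume
  fractions;
- the same t-test on the per-replicate contact occupancies.

Writes results/statistics.json. Run 01–03 first.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from pocketdyn.stats import compare_success_counts, ttest_equal_var_two_tailed

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    success = pd.read_csv(RESULTS / "docking_success.tsv", sep="\t").set_index("condition")
    volumes = pd.read_csv(RESULTS / "volume_subsamples.tsv", sep="\t")
    contacts = pd.read_csv(RESULTS / "contact_occupancy.tsv", sep="\t")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        binom = compare_success_counts(
            int(success.loc["occluded", "n_success"]),
            int(success.loc["occluded", "n_replicates"]),
            int(success.loc["open", "n_success"]),
            int(success.loc["open", "n_replicates"]),
        )

    vol_open = volumes.query("condition == 'open'")["large_volume_fraction"]
    vol_occ = volumes.query("condition == 'occluded'")["large_volume_fraction"]
    t_vol = ttest_equal_var_two_tailed(vol_open, vol_occ)

    c_open = contacts.query("condition == 'open'")["fraction"]
    c_occ = contacts.query("condition == 'occluded'")["fraction"]
    t_contact = ttest_equal_var_two_tailed(c_open, c_occ)

    payload = {
        "docking_binomial": {
            "k": binom.k,
            "n": binom.n,
            "p0": binom.p0,
            "p_upper_tail": binom.p_upper_tail,
            "construction": binom.construction,
        },
        "large_volume_ttest": {
            "t": t_vol.t,
            "df": t_vol.df,
            "p_two_tailed": t_vol.p_two_tailed,
        },
        "contact_occupancy_ttest": {
            "t": t_contact.t,
            "df": t_contact.df,
            "p_two_tailed": t_contact.p_two_tailed,
        },
    }
    out = RESULTS / "statistics.json"
    out.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"docking: binomial p = {binom.p_upper_tail:.3g} ({binom.construction})")
    print(f"large volumes: t = {t_vol.t:.3f}, p = {t_vol.p_two_tailed:.3g}")
    print(f"contacts: t = {t_contact.t:.3f}, p = {t_contact.p_two_tailed:.3g}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
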