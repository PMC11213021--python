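"""Test whether correlated motions are enriched inside the coevolving group.

Maps every residue pair's |DCC| to its IC category (pairs within two sequence
positions excluded), then runs the Mann-Whitney contrast battery within each
condition and between conditions: the coevolving network should be enriched
in the baseline, and selectively lose that enrichment in the knockdown.

Reads results/sca/ and results/dcc/, writes results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from sectordyn.compare import (
    categorize_pairs,
    category_distributions,
    compare_between_conditions,
    compare_within_condition,
    plot_category_distributions,
    write_pair_table,
    write_report,
)
from sectordyn.evaluation import assignment_from_ground_truth
from sectordyn.trajectory import read_dcc

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    mem = pd.read_csv(ROOT / "sca" / "ic_membership.tsv", sep="\t")
    k = int(mem["ic_id"].max())
    dists = {}
    for cond in ("baseline", "knockdown"):
        dcc = read_dcc(ROOT / "dcc" / f"dcc_{cond}.tsv")
        ics = assignment_from_ground_truth(
            sorted(mem["ref_residue_number"]), len(dcc.residue_numbers)
        )
        # keep the SCA-derived IC structure (k ICs) rather than one pooled set
        ics.memberships = [
            sorted(mem.loc[mem["ic_id"] == i, "ref_residue_number"])
            for i in range(1, k + 1)
        ]
        pairs = categorize_pairs(dcc, ics, min_separation=2)
        write_pair_table(pairs, out / f"pairs_{cond}.tsv")
        dists[cond] = category_distributions(pairs, n_ics=k)
        report = compare_within_condition(dists[cond])
        write_report(report, out / f"within_{cond}.tsv")
        plot_category_distributions(
            dists[cond], out / f"categories_{cond}.png", cond
        )
        print(f"--- within {cond} ---")
        print(report[["contrast", "n", "m", "mean_a", "mean_b",
                      "p_two_sided", "stars"]].to_string(index=False))

    between = compare_between_conditions(
        dists["baseline"], dists["knockdown"], "baseline", "knockdown"
    )
    write_report(between, out / "between_conditions.tsv")
    print("--- between conditions ---")
    print(between[["contrast", "mean_a", "mean_b", "p_two_sided",
                   "stars"]].to_string(index=False))
    print(f"wrote enrichment reports under {out}")


if __name__ == "__main__":
    main()
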