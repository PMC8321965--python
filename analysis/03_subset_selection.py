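"""Greedy subset search and selection of the brief anxiety/depression items.

Builds nested candidate subsets by removing the weakest eligible item one at
a time, evaluates each subset's sum score with subgroup ROC analyses
(overall, by gender, by age group), and selects the final adolescent-report
subsets, verifying the same items on parent-report.
"""

import json

import pandas as pd

from _common import load_cohort, parse_args
from rcads_brief.pipeline import derive_screen


def main() -> None:
    args = parse_args(__doc__)
    cohort = load_cohort(args)
    result = derive_screen(cohort)

    rows = []
    summary = {}
    for scale, deriv in (("anxiety", result.anxiety),
                         ("depression", result.depression)):
        for informant, evals in deriv.evaluations.items():
            for e in evals:
                row = e.row()
                row["scale"] = scale
                rows.append(row)
        if deriv.selection is None:
            summary[scale] = {"selection_failure": deriv.failure}
            print(f"{scale}: no subset met the criteria ({deriv.failure})")
            continue
        sel = deriv.selection
        o = sel.adolescent.overall
        summary[scale] = {
            "selected_items": list(sel.adolescent.items),
            "n_items": sel.adolescent.size,
            "auc": o["roc"].auc,
            "cutoff": o["cutoff"].cutoff,
            "sensitivity": o["cutoff"].sensitivity,
            "specificity": o["cutoff"].specificity,
            "tier": o["cutoff"].tier,
            "parent_same_items_meets_criteria": sel.shared_set_retained,
            "parent_optimal_items": list(sel.parent_optimal.items),
        }
        print(f"{scale}: selected {sel.adolescent.size} items "
              f"(AUC {o['roc'].auc:.2f}, cut-off {o['cutoff'].cutoff}, "
              f"sens/spec {o['cutoff'].sensitivity:.2f}/"
              f"{o['cutoff'].specificity:.2f}, tier {o['cutoff'].tier}); "
              f"shared set retained on parent-report: {sel.shared_set_retained}")

    pd.DataFrame(rows).to_csv(args.results / "subset_evaluations.csv", index=False)
    (args.results / "subset_selection.json").write_text(
        json.dumps(summary, indent=2, default=float))
    print(f"wrote {args.results / 'subset_evaluations.csv'} and subset_selection.json")


if __name__ == "__main__":
    main()
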