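"""Psychometric evaluation of the brief screen against the full-length scales.

McDonald's omega (with person-bootstrap CIs) per sample, convergent/
divergent Pearson validity against the MFQ total, criterion-validity ROC
grids for the brief, full (47-item) and anxiety/depression scale scores,
and the completer vs partial-completer MCAR comparability check.
"""

import json

import pandas as pd

from _common import SCREEN_ANX, SCREEN_DEP, load_cohort, parse_args
from rcads_brief.psychometrics import (ScaleDefinition,
                                       compare_scales_criterion,
                                       convergent_divergent, mcdonald_omega,
                                       missingness_comparability)


def main() -> None:
    args = parse_args(__doc__)
    cohort = load_cohort(args)
    bank = cohort.bank

    brief_total = SCREEN_ANX + SCREEN_DEP
    scales = {
        "brief_anxiety_6": SCREEN_ANX,
        "brief_depression_5": SCREEN_DEP,
        "brief_total_11": brief_total,
        "rcads_anxiety_37": tuple(bank.rcads_anxiety_items(True)),
        "rcads_depression_10": tuple(bank.rcads_depression_items()),
        "rcads_total_47": tuple(bank.rcads_total_items()),
    }

    omega_rows = []
    for name, items in scales.items():
        for informant in ("adolescent", "parent"):
            sd = ScaleDefinition(name, tuple(items), informant)
            for sample in ("community", "clinic", "clinic_anxiety",
                           "clinic_depression"):
                try:
                    res = mcdonald_omega(cohort, sd, sample=sample, n_boot=400,
                                         seed=args.seed, min_persons=30)
                except ValueError:
                    # subsample too small for this scale's complete cases
                    continue
                omega_rows.append({
                    "scale": name, "informant": informant, "sample": sample,
                    "omega": res.omega, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "n": res.n_persons,
                })
    omega = pd.DataFrame(omega_rows)
    omega.to_csv(args.results / "omega.csv", index=False)
    brief = omega.query("scale == 'brief_total_11' and informant == 'adolescent'")
    print("omega, 11-item total: "
          + ", ".join(f"{r.sample}={r.omega:.2f}" for r in brief.itertuples()))

    validity = convergent_divergent(
        cohort,
        [ScaleDefinition(n, tuple(i)) for n, i in scales.items()])
    validity.to_csv(args.results / "validity.csv", index=False)
    conv = validity.query("scale == 'brief_depression_5' and sample == 'community'")
    print(f"brief depression vs MFQ total (community): r = {conv.iloc[0]['r']:.2f}")

    grids = []
    for flag, names in (("anxiety", ["brief_anxiety_6", "rcads_anxiety_37"]),
                        ("depression", ["brief_depression_5", "rcads_depression_10"]),
                        ("any", ["brief_total_11", "rcads_total_47"])):
        defs = [ScaleDefinition(n, tuple(scales[n]), inf)
                for n in names for inf in ("adolescent", "parent")]
        g = compare_scales_criterion(cohort, defs, flag)
        g.insert(0, "case_flag", flag)
        grids.append(g)
    grid = pd.concat(grids, ignore_index=True)
    grid.to_csv(args.results / "criterion_grid.csv", index=False)
    top = grid.query("scale == 'brief_total_11' and informant == 'adolescent' "
                     "and stratum == 'overall'").iloc[0]
    print(f"11-item total vs any diagnosis: AUC {top.auc:.2f}, cut-off "
          f"{top.cutoff}, sens/spec {top.sensitivity:.2f}/{top.specificity:.2f}")

    mcar = missingness_comparability(cohort)
    mcar["tests"].to_csv(args.results / "mcar_checks.csv", index=False)
    print(f"MCAR-consistent: {mcar['mcar_consistent']}")
    (args.results / "mcar_flag.json").write_text(
        json.dumps({"mcar_consistent": mcar["mcar_consistent"]}))
    print(f"wrote omega.csv, validity.csv, criterion_grid.csv, mcar_checks.csv "
          f"in {args.results}")


if __name__ == "__main__":
    main()
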