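"""Add-on item screening and incremental-validity tests.

Screens the suicidal-ideation (MFQ, rescaled 0-3), symptom-impact and
duration items by discrimination and missingness, then asks with nested
logistic regressions whether (1) the best suicidal-ideation item improves
the brief depression score, (2) the two impact items improve the 11-item
total, and (3) parent-report adds to adolescent-report.
"""

import json

from _common import (SCREEN_ANX, SCREEN_DEP, SCREEN_IMPACT, load_cohort,
                     parse_args)
from rcads_brief.augmentation import (combine_informants, incremental_test,
                                      screen_addon_items)

SCREEN_11 = list(SCREEN_ANX) + list(SCREEN_DEP)


def lr_entry(reduced, full, test):
    return {
        "predictors_reduced": list(reduced.predictors),
        "predictors_full": list(full.predictors),
        "odds_ratios": dict(full.odds_ratios),
        "chi_square": test.chi_square,
        "df": test.df,
        "p": test.p_value,
        "significant_at_0.01": test.significant,
        "n_used": full.n_used,
    }


def main() -> None:
    args = parse_args(__doc__)
    cohort = load_cohort(args)
    bank = cohort.bank
    report = {}

    suicide = screen_addon_items(cohort, bank.mfq_items(), "depression")
    impact = screen_addon_items(
        cohort, bank.impact_items() + bank.duration_items(), "any")
    report["addon_screening"] = {
        "suicidal_ideation": suicide.to_dict("records"),
        "impact_duration": impact.to_dict("records"),
    }
    print("add-on discrimination (vs depression):")
    print(suicide.to_string(index=False))
    print("impact/duration discrimination (vs any diagnosis):")
    print(impact.to_string(index=False))

    best_suicide = suicide.iloc[0]["item_id"]
    r, f, t = incremental_test(cohort, SCREEN_DEP, [best_suicide], "depression")
    report["suicidal_ideation_over_depression_items"] = lr_entry(r, f, t)
    print(f"\n{best_suicide} over the 5 depression items: "
          f"chi2({t.df}) = {t.chi_square:.2f}, p = {t.p_value:.3f} "
          f"({'significant' if t.significant else 'not significant'} at 0.01)")

    r, f, t = incremental_test(cohort, SCREEN_11, list(SCREEN_IMPACT), "any")
    report["impact_over_total_items"] = lr_entry(r, f, t)
    print(f"impact items over the 11-item total: chi2({t.df}) = "
          f"{t.chi_square:.2f}, p = {t.p_value:.4f} "
          f"({'significant' if t.significant else 'not significant'} at 0.01)")

    for flag in ("anxiety", "depression", "any"):
        items = {"anxiety": list(SCREEN_ANX), "depression": list(SCREEN_DEP),
                 "any": SCREEN_11}[flag]
        r, f, t = combine_informants(cohort, items, flag)
        report[f"combine_informants_{flag}"] = lr_entry(r, f, t)
        print(f"parent-report added to adolescent-report ({flag}): "
              f"chi2({t.df}) = {t.chi_square:.2f}, p = {t.p_value:.4f}, "
              f"ORs {dict((k, round(v, 2)) for k, v in f.odds_ratios.items())}")

    (args.results / "augmentation.json").write_text(
        json.dumps(report, indent=2, default=float))
    print(f"wrote {args.results / 'augmentation.json'}")


if __name__ == "__main__":
    main()
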