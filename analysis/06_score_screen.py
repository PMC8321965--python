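"""Derive gender-specific cut-offs on the synthetic cohort and score everyone.

Builds a scoreable screen definition (the 11 planted items plus the distress
and school-interference impact items) with integer >=-rule cut-offs derived
per informant and gender from the cohort's tiered ROC analyses, then scores
every respondent with the published screen and reports positive rates.
"""

import json

from _common import (SCREEN_ANX, SCREEN_DEP, SCREEN_IMPACT, load_cohort,
                     parse_args)
from rcads_brief.pipeline import derived_cutoff_table
from rcads_brief.scoring import default_screen, score_frame, write_results


def main() -> None:
    args = parse_args(__doc__)
    cohort = load_cohort(args)

    derived = derived_cutoff_table(cohort, SCREEN_ANX, SCREEN_DEP, SCREEN_IMPACT)
    derived.to_json(args.results / "derived_screen.json")
    print("cut-offs derived from the synthetic cohort (score >= threshold):")
    for (informant, gender, scale), thr in sorted(derived.cutoffs.items()):
        print(f"  {informant:10s} {gender:6s} {scale:18s} >= {thr}")

    results = score_frame(cohort, default_screen())
    write_results(results, args.results / "screen_results.csv")
    defined = [r for r in results if r.total_positive is not None]
    pos = sum(r.total_positive for r in defined)
    adv = sum(1 for r in results if r.risk_advisory)
    print(f"\nscored {len(results)} respondent records with the published screen:")
    print(f"  total-score positive: {pos}/{len(defined)} with defined scores")
    print(f"  risk advisories issued (positive depression score): {adv}")
    print(f"wrote {args.results / 'screen_results.csv'} and derived_screen.json")


if __name__ == "__main__":
    main()
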