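"""Per-item reduction statistics and the eligible item pools.

For each candidate item (31 non-OCD anxiety, 10 depression), per informant:
item-total correlation, point-biserial discrimination against the relevant
diagnosis, partials controlling gender and age, and missingness; then the
retention rule (> 0.70 item-total OR > 0.30 discrimination, < 10% missing).
"""

import json

import pandas as pd

from _common import load_cohort, parse_args
from rcads_brief.reduction import item_stats_table, retain_items


def main() -> None:
    args = parse_args(__doc__)
    cohort = load_cohort(args)
    bank = cohort.bank

    pools = {
        "anxiety": (bank.rcads_anxiety_items(include_ocd=False),
                    bank.rcads_anxiety_items(include_ocd=True), "anxiety"),
        "depression": (bank.rcads_depression_items(),
                       bank.rcads_depression_items(), "depression"),
    }
    tables = []
    eligible: dict[str, dict[str, list[str]]] = {}
    for scale, (pool, total, flag) in pools.items():
        eligible[scale] = {}
        for informant in ("adolescent", "parent"):
            t = item_stats_table(cohort, pool, total, flag, informant=informant)
            kept = sorted(retain_items(t))
            eligible[scale][informant] = kept
            t.insert(0, "scale", scale)
            t.insert(1, "informant", informant)
            tables.append(t)
            print(f"{scale:10s} {informant:10s}: {len(kept)}/{len(pool)} items "
                  f"eligible (top: {t.iloc[0]['item_id']} "
                  f"rpb={t.iloc[0]['discrimination_rpb']:.2f})")

    stats = pd.concat(tables, ignore_index=True)
    stats.to_csv(args.results / "item_stats.csv", index=False)
    (args.results / "eligible_pools.json").write_text(json.dumps(eligible, indent=2))
    print(f"wrote {args.results / 'item_stats.csv'} and eligible_pools.json")


if __name__ == "__main__":
    main()
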