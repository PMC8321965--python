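"""Shared plumbing for the analysis drivers."""

from __future__ import annotations

import argparse
from pathlib import Path

from rcads_brief.bank import default_item_bank
from rcads_brief.cohort import default_config, generate_cohort
from rcads_brief.scoring import read_responses, write_responses

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_CSV = "cohort.csv"

SCREEN_ANX = ("RCADS18", "RCADS45", "RCADS35", "RCADS34", "RCADS24", "RCADS20")
SCREEN_DEP = ("RCADS19", "RCADS6", "RCADS29", "RCADS2", "RCADS21")
SCREEN_IMPACT = ("IMP_DISTRESS", "IMP_SCHOOL")


def parse_args(description: str) -> argparse.Namespace:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--results", type=Path, default=RESULTS)
    return p.parse_args()


def load_cohort(args):
    """Use the simulated cohort on disk, or regenerate it from the seed."""
    path = args.results / COHORT_CSV
    bank = default_item_bank()
    if path.exists():
        return read_responses(path, bank)
    args.results.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(default_config(bank, seed=args.seed), bank)
    write_responses(cohort, path)
    return cohort
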