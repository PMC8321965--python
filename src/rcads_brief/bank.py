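"""Item bank for the instruments used to derive and evaluate the brief screen.

The default bank carries the 47 RCADS items (0-3 response scale) with their
disorder subscales, the four MFQ suicidal-ideation items (0-2 raw scale),
and the seven symptom impact/duration questions (0-3).
"""

from __future__ import annotations

from dataclasses import dataclass, field


RCADS = "RCADS"
MFQ = "MFQ"
IMPACT = "IMPACT"
DURATION = "DURATION"

_INSTRUMENTS = {RCADS, MFQ, IMPACT, DURATION}
_SUBSCALES = {"GAD", "PD", "SOC", "SEP", "OCD", "MDD", "SUICIDE", "IMPACT", "DURATION"}


@dataclass(frozen=True)
class Item:
    item_id: str
    instrument: str
    subscale: str
    min_score: int = 0
    max_score: int = 3
    text: str = ""

    def __post_init__(self) -> None:
        if self.instrument not in _INSTRUMENTS:
            raise ValueError(f"unknown instrument {self.instrument!r} for {self.item_id}")
        if self.subscale not in _SUBSCALES:
            raise ValueError(f"unknown subscale {self.subscale!r} for {self.item_id}")
        if self.max_score <= self.min_score:
            raise ValueError(f"degenerate score range for {self.item_id}")

    @property
    def n_categories(self) -> int:
        return self.max_score - self.min_score + 1


@dataclass(frozen=True)
class ItemBank:
    items: tuple[Item, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item_ids in bank: {dupes}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __contains__(self, item_id: str) -> bool:
        return any(it.item_id == item_id for it in self.items)

    def get(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def ids_by(self, *, instrument: str | None = None, subscale: str | None = None) -> list[str]:
        out = []
        for it in self.items:
            if instrument is not None and it.instrument != instrument:
                continue
            if subscale is not None and it.subscale != subscale:
                continue
            out.append(it.item_id)
        return out

    # -- conventional pools -------------------------------------------------

    def rcads_anxiety_items(self, include_ocd: bool = True) -> list[str]:
        """The RCADS anxiety scale: 37 items with OCD, 31 without.

        OCD items are excluded from the candidate pool for screen derivation
        (OCD is not an anxiety disorder under DSM-5) but still count toward
        the conventional anxiety total score.
        """
        subs = {"GAD", "PD", "SOC", "SEP"} | ({"OCD"} if include_ocd else set())
        return [it.item_id for it in self.items if it.instrument == RCADS and it.subscale in subs]

    def rcads_depression_items(self) -> list[str]:
        return self.ids_by(instrument=RCADS, subscale="MDD")

    def rcads_total_items(self) -> list[str]:
        return self.ids_by(instrument=RCADS)

    def mfq_items(self) -> list[str]:
        return self.ids_by(instrument=MFQ)

    def impact_items(self) -> list[str]:
        return self.ids_by(instrument=IMPACT)

    def duration_items(self) -> list[str]:
        return self.ids_by(instrument=DURATION)


# RCADS subscale membership (item number -> subscale).
_RCADS_SUBSCALES: dict[int, str] = {
    # generalised anxiety
    1: "GAD", 13: "GAD", 22: "GAD", 27: "GAD", 35: "GAD", 37: "GAD",
    # panic disorder
    3: "PD", 14: "PD", 24: "PD", 26: "PD", 28: "PD", 34: "PD", 36: "PD", 39: "PD", 41: "PD",
    # social anxiety
    4: "SOC", 7: "SOC", 8: "SOC", 12: "SOC", 20: "SOC", 30: "SOC", 32: "SOC", 38: "SOC", 43: "SOC",
    # separation anxiety
    5: "SEP", 9: "SEP", 17: "SEP", 18: "SEP", 33: "SEP", 45: "SEP", 46: "SEP",
    # obsessive-compulsive
    10: "OCD", 16: "OCD", 23: "OCD", 31: "OCD", 42: "OCD", 44: "OCD",
    # major depression
    2: "MDD", 6: "MDD", 11: "MDD", 15: "MDD", 19: "MDD", 21: "MDD",
    25: "MDD", 29: "MDD", 40: "MDD", 47: "MDD",
}

_RCADS_TEXT: dict[int, str] = {
    1: "I worry about things",
    2: "I feel sad or empty",
    3: "When I have a problem, I get a funny feeling in my stomach",
    4: "I worry when I think I have done poorly at something",
    5: "I would feel afraid of being on my own at home",
    6: "Nothing is much fun anymore",
    7: "I feel scared when I have to take a test",
    8: "I feel worried when I think someone is angry with me",
    9: "I worry about being away from my parents",
    11: "I have trouble sleeping",
    12: "I worry that I will do badly at my school work",
    13: "I worry that something awful will happen to someone in my family",
    14: "I suddenly feel as if I can't breathe when there is no reason for this",
    15: "I have problems with my appetite",
    17: "I feel scared if I have to sleep on my own",
    18: "I have trouble going to school in the mornings because I feel nervous or afraid",
    19: "I have no energy for things",
    20: "I worry I might look foolish",
    21: "I am tired a lot",
    22: "I worry that bad things will happen to me",
    24: "When I have a problem, my heart beats really fast",
    25: "I cannot think clearly",
    26: "I suddenly start to tremble or shake when there is no reason for this",
    27: "I worry that something bad will happen to me",
    28: "When I have a problem, I feel shaky",
    29: "I feel worthless",
    30: "I worry about making mistakes",
    32: "I worry what other people think of me",
    33: "I am afraid of being in crowded places",
    34: "All of a sudden I feel really scared for no reason at all",
    35: "I worry about what is going to happen",
    36: "I suddenly become dizzy or faint when there is no reason for this",
    37: "I think about death",
    38: "I feel afraid if I have to talk in front of my class",
    39: "My heart suddenly starts to beat too quickly for no reason",
    40: "I feel like I don't want to move",
    41: "I worry that I will suddenly get a scared feeling when there is nothing to be afraid of",
    43: "I feel afraid that I will make a fool of myself in front of people",
    45: "I worry when I go to bed at night",
    46: "I would feel scared if I had to stay away from home overnight",
    47: "I feel restless",
}

_MFQ_SUICIDE: list[tuple[str, str]] = [
    ("MFQ19", "thought about killing self"),
    ("MFQ21", "thought about death or dying"),
    ("MFQ15", "thought family would be better off without self"),
    ("MFQ16", "thought life was not worth living"),
]

_IMPACT_ITEMS: list[tuple[str, str]] = [
    ("IMP_DISTRESS", "How much do these difficulties upset or distress you?"),
    ("IMP_HOME", "How much do these difficulties get in the way of your everyday life at home?"),
    ("IMP_SCHOOL", "How much do these difficulties get in the way of your everyday life at school?"),
    ("IMP_FRIENDS", "How much do these difficulties get in the way of your friendships?"),
    ("IMP_OUTSIDE", "How much do these difficulties get in the way of activities outside school?"),
]

_DURATION_ITEMS: list[tuple[str, str]] = [
    ("DUR_ANX", "How long have the anxiety symptoms been present?"),
    ("DUR_DEP", "How long have the low-mood symptoms been present?"),
]


def default_item_bank() -> ItemBank:
    """Build the default 58-item bank.

    47 RCADS items (six subscales, 0-3), four MFQ suicidal-ideation items
    (raw 0-2), five symptom-impact items and two duration items (0-3).
    """
    items: list[Item] = []
    for n in range(1, 48):
        items.append(
            Item(
                item_id=f"RCADS{n}",
                instrument=RCADS,
                subscale=_RCADS_SUBSCALES[n],
                min_score=0,
                max_score=3,
                text=_RCADS_TEXT.get(n, ""),
            )
        )
    for item_id, text in _MFQ_SUICIDE:
        items.append(Item(item_id=item_id, instrument=MFQ, subscale="SUICIDE",
                          min_score=0, max_score=2, text=text))
    for item_id, text in _IMPACT_ITEMS:
        items.append(Item(item_id=item_id, instrument=IMPACT, subscale="IMPACT",
                          min_score=0, max_score=3, text=text))
    for item_id, text in _DURATION_ITEMS:
        items.append(Item(item_id=item_id, instrument=DURATION, subscale="DURATION",
                          min_score=0, max_score=3, text=text))
    return ItemBank(items=tuple(items))
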