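"""Literature-triple triangulation.

Subject-predicate-object assertions mined from the literature ("triples")
are intersected for an exposure and a cancer: terms appearing as the object
of an exposure-side triple and the subject of a cancer-side triple (or vice
versa) are candidate mediating terms. A combined literature space is viable
when it holds strictly more than 50 triples. Matching is exact string match
after case-folding — no concept normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_summary import InputError

VIABILITY_THRESHOLD = 50

TRIPLE_COLUMNS = ["subject", "predicate", "object", "mention_count"]


@dataclass
class TripleSet:
    anchor_term: str
    triples: pd.DataFrame  # subject, predicate, object, mention_count

    def __post_init__(self) -> None:
        t = self.triples.copy()
        for col in ("subject", "predicate", "object"):
            t[col] = t[col].astype(str).str.casefold().str.strip()
        if "mention_count" not in t.columns:
            t["mention_count"] = 1
        if (t["mention_count"] < 1).any():
            raise InputError("mention_count must be >= 1")
        t = t.drop_duplicates(subset=["subject", "predicate", "object"])
        self.triples = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.triples)


def read_triples(path, anchor_term: str, sep: str = "\t") -> TripleSet:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TRIPLE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise InputError(f"triples file lacks column(s): {missing}")
    return TripleSet(anchor_term, df)


def overlap_triples(
    exposure: TripleSet,
    cancer: TripleSet,
    mode: str = "bridge",
) -> pd.DataFrame:
    """Common terms between the two literature spaces, ranked by mentions.

    ``mode='bridge'`` (default): a term must appear as object on one side and
    subject on the other (either direction), i.e. it can sit on a path
    exposure -> term -> cancer or cancer -> term -> exposure.
    ``mode='any'``: any term shared between the two spaces counts.
    Ties in summed mention_count break lexicographically.
    """
    if len(exposure) == 0 or len(cancer) == 0:
        raise InputError("both triple sets must be non-empty")

    def side_terms(ts: TripleSet, role: str) -> pd.Series:
        return ts.triples.groupby(role)["mention_count"].sum()

    if mode == "bridge":
        pairs = [("object", "subject"), ("subject", "object")]
    elif mode == "any":
        pairs = [(a, b) for a in ("subject", "object") for b in ("subject", "object")]
    else:
        raise InputError(f"unknown overlap mode {mode!r}")

    rows: dict[str, dict] = {}
    for exp_role, can_role in pairs:
        e = side_terms(exposure, exp_role)
        c = side_terms(cancer, can_role)
        for term in e.index.intersection(c.index):
            entry = rows.setdefault(term, {"term": term, "mention_count": 0,
                                           "directions": set()})
            entry["mention_count"] = max(
                entry["mention_count"], int(e[term] + c[term]))
            entry["directions"].add(f"exposure_{exp_role}->cancer_{can_role}")

    out = pd.DataFrame(
        [{"term": r["term"], "mention_count": r["mention_count"],
          "directions": ";".join(sorted(r["directions"]))}
         for r in rows.values()],
        columns=["term", "mention_count", "directions"],
    )
    return out.sort_values(
        ["mention_count", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def supporting_triples(exposure: TripleSet, cancer: TripleSet, term: str) -> dict:
    """The triples on each side that involve ``term``."""
    t = str(term).casefold().strip()

    def pick(ts: TripleSet) -> pd.DataFrame:
        m = (ts.triples["subject"] == t) | (ts.triples["object"] == t)
        return ts.triples.loc[m].reset_index(drop=True)

    return {"exposure": pick(exposure), "cancer": pick(cancer)}


def assess_viability(combined_size: int,
                     threshold: int = VIABILITY_THRESHOLD) -> tuple[bool, int]:
    """A literature space is viable iff it holds > ``threshold`` triples."""
    return combined_size > threshold, combined_size


def combine_spaces(exposure: TripleSet, cancer: TripleSet) -> int:
    """Size of the combined (deduplicated) literature space."""
    merged = pd.concat([exposure.triples, cancer.triples]).drop_duplicates(
        subset=["subject", "predicate", "object"])
    return len(merged)


def sankey_edges(exposure: TripleSet, cancer: TripleSet,
                 overlap: pd.DataFrame) -> pd.DataFrame:
    """Edge list (source, target, weight) for flow-diagram export."""
    edges = []
    for term in overlap["term"]:
        sup = supporting_triples(exposure, cancer, term)
        for _, r in sup["exposure"].iterrows():
            edges.append({"source": r["subject"], "target": r["object"],
                          "weight": int(r["mention_count"])})
        for _, r in sup["cancer"].iterrows():
            edges.append({"source": r["subject"], "target": r["object"],
                          "weight": int(r["mention_count"])})
    return pd.DataFrame(edges, columns=["source", "target", "weight"]).drop_duplicates()
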