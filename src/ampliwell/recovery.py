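"""Recovery estimation against a culture-independent community profile.

The profile lists short (~250 nt, V4-region) representative sequences of
community OTUs with their relative abundances per plant compartment.
Each representative is aligned semi-globally against every collection
sequence — the short fragment is scored over its own length inside the
near-full-length 16S sequence — and pairs at >= 97% identity are hits.
The recovery estimate of a compartment is the summed relative abundance
of its profile OTUs with at least one hit: the fraction of the natural
community, by abundance, that the culture collection represents.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .seqkernel import db_search

CROSSREF_THRESHOLD = 97.0

PROFILE_COLUMNS = ["profile_otu_id", "representative", "compartment", "relative_abundance"]


class ProfileError(ValueError):
    pass


def load_profile(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ProfileError(f"profile missing columns: {sorted(missing)}")
    validate_profile(df)
    return df


def validate_profile(profile: pd.DataFrame) -> None:
    if profile.empty:
        raise ProfileError("community profile is empty")
    if (profile["relative_abundance"] < 0).any():
        raise ProfileError("negative relative abundance")
    sums = profile.groupby("compartment")["relative_abundance"].sum()
    bad = sums[sums > 1.0 + 1e-6]
    if not bad.empty:
        raise ProfileError(
            f"abundances exceed 1 in compartments: {list(bad.index)}"
        )


def crossref(
    collection: list[tuple[str, str]],
    profile: pd.DataFrame,
    threshold: float = CROSSREF_THRESHOLD,
) -> pd.DataFrame:
    """Hit table: profile OTU x best collection sequence at >= threshold.

    The profile representative is the query so identity is scored over
    the short fragment's own length.
    """
    validate_profile(profile)
    rows = []
    for _, rec in profile.iterrows():
        if not collection:
            break
        hit = db_search(rec["representative"], collection, identity_threshold=threshold)
        if hit is not None:
            rows.append(
                dict(
                    profile_otu_id=rec["profile_otu_id"],
                    compartment=rec["compartment"],
                    collection_id=hit.hit_id,
                    identity=hit.alignment.identity,
                )
            )
    return pd.DataFrame(
        rows, columns=["profile_otu_id", "compartment", "collection_id", "identity"]
    )


@dataclass
class RecoveryReport:
    per_compartment: pd.DataFrame  # compartment, recovered_percent, n_hit, n_total
    hits: pd.DataFrame

    def recovered_percent(self, compartment: str) -> float:
        sel = self.per_compartment[
            self.per_compartment["compartment"] == compartment
        ]
        if sel.empty:
            raise KeyError(compartment)
        return float(sel["recovered_percent"].iloc[0])


def recovery_estimate(hits: pd.DataFrame, profile: pd.DataFrame) -> RecoveryReport:
    """Per-compartment recovered abundance (%): each profile OTU counts
    once no matter how many collection sequences hit it."""
    validate_profile(profile)
    hit_otus = set(hits["profile_otu_id"]) if not hits.empty else set()
    rows = []
    for comp, group in profile.groupby("compartment", sort=True):
        mask = group["profile_otu_id"].isin(hit_otus)
        rows.append(
            dict(
                compartment=comp,
                recovered_percent=100.0 * float(group.loc[mask, "relative_abundance"].sum()),
                n_hit_otus=int(mask.sum()),
                n_profile_otus=len(group),
            )
        )
    report = pd.DataFrame(
        rows, columns=["compartment", "recovered_percent", "n_hit_otus", "n_profile_otus"]
    )
    return RecoveryReport(report, hits)
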