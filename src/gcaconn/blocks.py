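"""Exchangeability blocks for permutation inference under nested dependence.

Subjects are nested as individuals within families within acquisition sites.
Admissible permutations (i) shuffle individuals within a family, and
(ii) swap whole families within a site, but only between families with an
identical signature (same size and twin status); subjects never move across
sites.  This reproduces the within-block / whole-block semantics of
permutation tools for multi-level designs, self-contained and checkable by
brute-force enumeration at small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExchangeabilityBlocks",
    "build_blocks",
    "sample_permutation",
    "sample_permutations",
    "enumerate_permutations",
    "count_permutations",
]


@dataclass
class ExchangeabilityBlocks:
    """Per-site signature groups of families (each family = sorted row indices)."""

    n: int
    # {site: {signature: [ [row indices of family 1], [family 2], ... ]}}
    groups: dict = field(default_factory=dict)

    def describe(self) -> str:
        lines = []
        for site, sigs in self.groups.items():
            parts = [f"{len(fams)} fam x sig{sig}" for sig, fams in sigs.items()]
            lines.append(f"{site}: " + ", ".join(parts))
        return "\n".join(lines)


def build_blocks(subject_table: pd.DataFrame) -> ExchangeabilityBlocks:
    """Derive the three-level nesting (site > family > individual).

    The family signature is (size, twin flag); only identically-signed
    families within the same site may exchange as whole blocks.
    """
    required = {"site", "family_id"}
    missing = required - set(subject_table.columns)
    if missing:
        raise ValueError(f"subject table lacks column(s) {sorted(missing)}")
    twin = (
        subject_table["twin"].astype(bool)
        if "twin" in subject_table.columns
        else pd.Series(False, index=subject_table.index)
    )
    fam_site = subject_table.groupby("family_id")["site"].nunique()
    if (fam_site > 1).any():
        bad = fam_site[fam_site > 1].index.tolist()
        raise ValueError(f"families straddle sites: {bad}")

    groups: dict = {}
    pos = pd.RangeIndex(len(subject_table))
    frame = subject_table.reset_index(drop=True).assign(_twin=twin.to_numpy(), _pos=pos)
    for site, site_df in frame.groupby("site", sort=True):
        sigs: dict = {}
        for fam, fam_df in site_df.groupby("family_id", sort=True):
            sig = (len(fam_df), bool(fam_df["_twin"].iloc[0]))
            sigs.setdefault(sig, []).append(sorted(fam_df["_pos"].tolist()))
        groups[site] = sigs
    return ExchangeabilityBlocks(n=len(subject_table), groups=groups)


def sample_permutation(
    blocks: ExchangeabilityBlocks, rng: np.random.Generator
) -> np.ndarray:
    """One admissible ordering, uniform over the admissible group.

    Returns ``perm`` such that permuted values are ``y[perm]``: the slots of
    family f receive the members of a same-signature family, internally
    shuffled.
    """
    perm = np.arange(blocks.n)
    for sigs in blocks.groups.values():
        for fams in sigs.values():
            order = rng.permutation(len(fams))
            for slot_idx, src_idx in enumerate(order):
                slots = fams[slot_idx]
                members = np.asarray(fams[src_idx])
                perm[slots] = members[rng.permutation(len(members))]
    return perm


def sample_permutations(
    blocks: ExchangeabilityBlocks, n_perm: int, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.stack([sample_permutation(blocks, rng) for _ in range(n_perm)])


def count_permutations(blocks: ExchangeabilityBlocks) -> int:
    """Size of the admissible group: prod over signature groups of m! * (s!)^m."""
    total = 1
    for sigs in blocks.groups.values():
        for (size, _twin), fams in sigs.items():
            total *= math.factorial(len(fams)) * math.factorial(size) ** len(fams)
    return total


def enumerate_permutations(
    blocks: ExchangeabilityBlocks, limit: int = 100_000
) -> np.ndarray:
    """Brute-force enumeration of every admissible ordering (small n only)."""
    total = count_permutations(blocks)
    if total > limit:
        raise ValueError(f"{total} admissible orderings exceed limit {limit}")

    def group_variants(fams: list) -> list[dict[int, int]]:
        """All assignments for one signature group, as slot->source maps."""
        out = []
        for fam_order in itertools.permutations(range(len(fams))):
            member_choices = [
                itertools.permutations(fams[src]) for src in fam_order
            ]
            for combo in itertools.product(*member_choices):
                mapping: dict[int, int] = {}
                for slot_idx, members in zip(range(len(fams)), combo):
                    for slot, src in zip(fams[slot_idx], members):
                        mapping[slot] = src
                out.append(mapping)
        return out

    all_groups = [
        group_variants(fams)
        for sigs in blocks.groups.values()
        for fams in sigs.values()
    ]
    perms = []
    for combo in itertools.product(*all_groups):
        perm = np.arange(blocks.n)
        for mapping in combo:
            for slot, src in mapping.items():
                perm[slot] = src
        perms.append(perm)
    return np.stack(perms)
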