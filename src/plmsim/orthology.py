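"""Orthology relationship analysis: LDO, concordance, and the ortholog conjecture.

Works from two-species orthogroup tables (InParanoid-style: a seed ortholog
pair plus inparalogs per species).  Groups are categorised by member counts
(one-to-one, one-to-two, one-to-many, many-to-many).  For one-to-two groups
the Least Diverged Ortholog (LDO) — the co-ortholog with the highest
sequence identity to the single-copy gene — is compared against the
co-ortholog with the highest embedding similarity; agreement is a
*concordant* pair, disagreement *discordant*.

The ortholog-conjecture analysis regresses embedding similarity on percent
identity per relationship category (single-pass OLS), flags pairs whose
residual exceeds k residual-SDs (default 3), and summarises similarity in
identity bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologGroup",
    "ConcordanceRecord",
    "OutlierFit",
    "read_ortholog_table",
    "write_ortholog_table",
    "classify_relationships",
    "find_ldo",
    "concordance",
    "concordance_from_records",
    "concordance_summary",
    "fit_and_flag_outliers",
    "fit_by_category",
    "bin_summary",
]

CATEGORIES = ("one-to-one", "one-to-two", "one-to-many", "many-to-many")


@dataclass(frozen=True)
class OrthologGroup:
    """A two-species orthogroup: seed pair plus inparalogs."""

    group_id: str
    species_a: str
    species_b: str
    members_a: tuple[str, ...]
    members_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members_a or not self.members_b:
            raise ValueError(f"group {self.group_id}: both member lists must be non-empty")
        object.__setattr__(self, "members_a", tuple(self.members_a))
        object.__setattr__(self, "members_b", tuple(self.members_b))

    @property
    def category(self) -> str:
        return classify_relationships(self)


def classify_relationships(group: OrthologGroup) -> str:
    """Relationship category from member counts.

    (1,1) one-to-one; (1,2) in either orientation one-to-two; (1,>=3)
    one-to-many; (>=2,>=2) many-to-many.
    """
    na, nb = len(group.members_a), len(group.members_b)
    if na == 0 or nb == 0:
        raise ValueError("empty member list")
    lo, hi = min(na, nb), max(na, nb)
    if lo == 1 and hi == 1:
        return "one-to-one"
    if lo == 1 and hi == 2:
        return "one-to-two"
    if lo == 1:
        return "one-to-many"
    return "many-to-many"


# ---------------------------------------------------------------------------
# Table I/O (canonical TSV: group_id, species, protein_id)


def read_ortholog_table(path: str | Path) -> list[OrthologGroup]:
    """Read an orthogroup table (TSV columns group_id, species, protein_id).

    This accepts both the InParanoiDB group-export dialect restricted to
    those columns and the canonical internal TSV.  Rows with missing fields
    are logged and skipped; groups without exactly two species are logged
    and skipped.  Raises if the file yields no valid group.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"group_id", "species", "protein_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
    n_bad = int(df[list(required)].isna().any(axis=1).sum())
    if n_bad:
        logger.warning("skipping %d malformed rows in %s", n_bad, path)
        df = df.dropna(subset=list(required))
    groups: list[OrthologGroup] = []
    n_skipped_groups = 0
    for gid, sub in df.groupby("group_id", sort=True):
        species = sorted(sub["species"].unique())
        if len(species) != 2:
            n_skipped_groups += 1
            continue
        members = {
            sp: tuple(sub.loc[sub["species"] == sp, "protein_id"]) for sp in species
        }
        groups.append(
            OrthologGroup(
                group_id=str(gid),
                species_a=species[0],
                species_b=species[1],
                members_a=members[species[0]],
                members_b=members[species[1]],
            )
        )
    if n_skipped_groups:
        logger.warning(
            "skipped %d groups without exactly two species in %s", n_skipped_groups, path
        )
    if not groups:
        raise ValueError(f"no valid two-species groups in {path}")
    return groups


def write_ortholog_table(path: str | Path, groups: Iterable[OrthologGroup]) -> None:
    rows = []
    for g in groups:
        for pid in g.members_a:
            rows.append({"group_id": g.group_id, "species": g.species_a, "protein_id": pid})
        for pid in g.members_b:
            rows.append({"group_id": g.group_id, "species": g.species_b, "protein_id": pid})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LDO and concordance


def find_ldo(
    single_copy_id: str,
    co_ortholog_ids: Sequence[str],
    identities: Mapping[str, float],
) -> tuple[str | None, bool]:
    """Least Diverged Ortholog: the co-ortholog with highest sequence identity.

    ``identities`` maps co-ortholog id -> identity with the single-copy
    gene.  Returns ``(ldo_id, tied)``; an exact tie for the maximum yields
    ``(None, True)``.
    """
    if len(co_ortholog_ids) < 2:
        raise ValueError("LDO is undefined for fewer than two co-orthologs")
    try:
        values = {cid: identities[cid] for cid in co_ortholog_ids}
    except KeyError as exc:
        raise KeyError(
            f"missing identity for co-ortholog {exc.args[0]!r} of {single_copy_id}"
        ) from exc
    best = max(values.values())
    winners = [cid for cid, v in values.items() if v == best]
    if len(winners) > 1:
        return None, True
    return winners[0], False


@dataclass(frozen=True)
class ConcordanceRecord:
    group_id: str
    single_copy_id: str
    ldo_id: str | None
    embedding_top_id: str | None
    status: str  # concordant | discordant | tied


def concordance(
    group: OrthologGroup,
    identities: Mapping[str, float],
    embedding_similarities: Mapping[str, float],
) -> ConcordanceRecord:
    """Compare identity-preferred vs embedding-preferred paralog in a one-to-two group.

    Both mappings are keyed by paralog id and hold that paralog's metric
    against the single-copy gene.  A tie in either metric yields status
    "tied".
    """
    if classify_relationships(group) != "one-to-two":
        raise ValueError(f"group {group.group_id} is not one-to-two")
    if len(group.members_a) == 1:
        single_copy = group.members_a[0]
        paralogs = group.members_b
    else:
        single_copy = group.members_b[0]
        paralogs = group.members_a
    ldo_id, tied_id = find_ldo(single_copy, paralogs, identities)
    emb_top, tied_emb = find_ldo(single_copy, paralogs, embedding_similarities)
    if tied_id or tied_emb:
        status = "tied"
    elif ldo_id == emb_top:
        status = "concordant"
    else:
        status = "discordant"
    return ConcordanceRecord(
        group_id=group.group_id,
        single_copy_id=single_copy,
        ldo_id=ldo_id,
        embedding_top_id=emb_top,
        status=status,
    )


def concordance_from_records(
    groups: Sequence[OrthologGroup], records: pd.DataFrame
) -> list[ConcordanceRecord]:
    """Concordance for every one-to-two group, metrics taken from a pair table.

    ``records`` needs columns ``group_id``, ``id_b`` (the co-member),
    ``identity_pct`` and ``similarity``, one row per (single-copy,
    co-member) pair, as produced by the synthetic orthogroup generator or
    by joining identity and similarity tables.
    """
    required = {"group_id", "id_b", "identity_pct", "similarity"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    out = []
    by_group = dict(tuple(records.groupby("group_id", sort=False)))
    for group in groups:
        if classify_relationships(group) != "one-to-two":
            continue
        sub = by_group.get(group.group_id)
        if sub is None:
            raise KeyError(f"no pair records for group {group.group_id}")
        identities = dict(zip(sub["id_b"], sub["identity_pct"]))
        sims = dict(zip(sub["id_b"], sub["similarity"]))
        out.append(concordance(group, identities, sims))
    return out


def concordance_summary(records: Sequence[ConcordanceRecord]) -> dict[str, float]:
    """Fractions of concordant / discordant / tied records (they sum to 1)."""
    if len(records) == 0:
        raise ValueError("no concordance records")
    n = len(records)
    counts = {"concordant": 0, "discordant": 0, "tied": 0}
    for rec in records:
        counts[rec.status] += 1
    return {status: counts[status] / n for status in counts}


# ---------------------------------------------------------------------------
# Ortholog-conjecture fit, outliers and binning


@dataclass(frozen=True)
class OutlierFit:
    """Per-category OLS of embedding similarity on identity with k-SD flags."""

    category: str
    slope: float
    intercept: float
    residual_sd: float
    k: float
    flagged_ids: tuple[str, ...]
    residuals: pd.Series = field(repr=False, default=None)


def fit_and_flag_outliers(
    points: pd.DataFrame, k: float = 3.0, *, category: str = ""
) -> OutlierFit:
    """OLS of ``similarity`` on ``identity_pct``; flag |residual| > k * SD.

    ``points`` needs columns ``identity_pct``, ``similarity`` and
    ``pair_id``.  The fit is single-pass over all points (prospective
    outliers included; no iterative refit) and the residual SD uses the
    N - 2 regression denominator.
    """
    required = {"identity_pct", "similarity", "pair_id"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"points table missing columns: {sorted(missing)}")
    n = len(points)
    if n < 3:
        raise ValueError("need at least 3 points to fit a line")
    x = points["identity_pct"].to_numpy(dtype=float)
    y = points["similarity"].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("zero identity variance: line of best fit is undefined")
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    sd = float(np.sqrt(np.sum(residuals**2) / (n - 2)))
    flagged = np.abs(residuals) > k * sd
    return OutlierFit(
        category=category,
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=sd,
        k=k,
        flagged_ids=tuple(points.loc[flagged, "pair_id"]),
        residuals=pd.Series(residuals, index=points["pair_id"].to_numpy()),
    )


def fit_by_category(points: pd.DataFrame, k: float = 3.0) -> dict[str, OutlierFit]:
    """Run :func:`fit_and_flag_outliers` separately per relationship category."""
    if "category" not in points.columns:
        raise ValueError("points table must carry a 'category' column")
    return {
        cat: fit_and_flag_outliers(sub, k, category=cat)
        for cat, sub in points.groupby("category", sort=True)
    }


def bin_summary(points: pd.DataFrame, bin_width: float = 10.0) -> pd.DataFrame:
    """Per-bin, per-category similarity summary over percent-identity bins.

    Bins are half-open ``[lo, lo + width)`` on percent identity; the last
    bin is closed at 100 so an identity of exactly 100 lands in it.
    Returns columns category, bin_lo, bin_hi, count, mean_similarity,
    median_similarity.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if len(points) == 0:
        raise ValueError("no points to summarise")
    df = points.copy()
    if "category" not in df.columns:
        df["category"] = "all"
    n_bins = int(np.ceil(100.0 / bin_width))
    idx = np.floor(df["identity_pct"].to_numpy(dtype=float) / bin_width).astype(int)
    idx = np.minimum(idx, n_bins - 1)  # closes the last bin at 100
    df["bin_lo"] = idx * bin_width
    df["bin_hi"] = np.minimum((idx + 1) * bin_width, 100.0)
    out = (
        df.groupby(["category", "bin_lo", "bin_hi"], sort=True)["similarity"]
        .agg(count="size", mean_similarity="mean", median_similarity="median")
        .reset_index()
    )
    return out
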