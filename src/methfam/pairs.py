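"""Relative-pair classification and intraclass correlations.

Relative pairs are enumerated from the pedigree (all within-family
combinations; optionally all cross-family pairs as "unrelated") and the
similarity of normalised methylation within each relationship class is
summarised by the one-way ANOVA intraclass correlation

    ICC = (MS_B - MS_W) / (MS_B + MS_W),

with pairs as the grouping factor. Under an additive genetic model the
expected class means are h2 for MZ twins, h2/2 for DZ twins, siblings and
parent-offspring pairs, and 0 for spouses and unrelated pairs.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .normalize import ResidualMatrix
from .pedigree import validate_pedigree

logger = logging.getLogger(__name__)

#: Expected coefficient on h2 for each relationship class.
EXPECTED_SHARE = {
    "MZ": 1.0,
    "DZ": 0.5,
    "sibling": 0.5,
    "parent_offspring": 0.5,
    "mother_offspring": 0.5,
    "father_offspring": 0.5,
    "spouse": 0.0,
    "unrelated": 0.0,
}

EXPECTED_LABEL = {1.0: "h^2", 0.5: "h^2/2", 0.0: "0"}


def classify_pairs(ped: pd.DataFrame, include_unrelated: bool = False) -> pd.DataFrame:
    """Enumerate relative pairs with relationship classes.

    Within-family pairs become MZ / DZ / sibling / parent_offspring / spouse;
    twin-to-non-twin-sibling pairs are "sibling" and parent-offspring pairs
    carry a ``subclass`` (mother_offspring / father_offspring). Spouses are
    founder couples sharing at least one child. With ``include_unrelated``
    every cross-family pair is emitted as "unrelated". Each unordered pair
    appears exactly once.
    """
    validate_pedigree(ped)
    rows = []
    info = ped.set_index("individual_id")

    for _, fam in ped.groupby("family_id", sort=True):
        ids = fam["individual_id"].tolist()
        for a, b in combinations(ids, 2):
            ra, rb = info.loc[a], info.loc[b]
            a_par = (ra["father_id"], ra["mother_id"])
            b_par = (rb["father_id"], rb["mother_id"])
            a_founder = pd.isna(a_par[0]) and pd.isna(a_par[1])
            b_founder = pd.isna(b_par[0]) and pd.isna(b_par[1])
            subclass = None
            if a_founder and b_founder:
                # Spouses: founders sharing at least one child.
                children = fam[(fam["father_id"].isin([a, b])) & (fam["mother_id"].isin([a, b]))]
                if len(children) == 0:
                    continue
                cls = "spouse"
            elif b in a_par or a in b_par:
                cls = "parent_offspring"
                parent = a if a in b_par else b
                subclass = (
                    "mother_offspring" if info.loc[parent, "sex"] == "female" else "father_offspring"
                )
            elif (
                not a_founder
                and not b_founder
                and a_par == b_par
            ):
                same_pair = (
                    pd.notna(ra["twin_pair_id"])
                    and ra["twin_pair_id"] == rb["twin_pair_id"]
                )
                if same_pair and ra["zygosity"] == "MZ_twin":
                    cls = "MZ"
                elif same_pair and ra["zygosity"] == "DZ_twin":
                    cls = "DZ"
                else:
                    cls = "sibling"
            else:
                # Within-family but not first degree (e.g. avuncular); out of
                # scope for the two-generation study design tables.
                continue
            rows.append((a, b, cls, subclass, EXPECTED_SHARE[cls]))

    if include_unrelated:
        fams = ped.groupby("family_id", sort=True)["individual_id"].apply(list)
        fam_list = fams.tolist()
        for i, j in combinations(range(len(fam_list)), 2):
            for a in fam_list[i]:
                for b in fam_list[j]:
                    rows.append((a, b, "unrelated", None, 0.0))

    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "relationship", "subclass", "expected_share"]
    )


def disjoint_pairs(pairs: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Greedy random subsample in which no individual appears twice.

    All-pairs enumeration reuses individuals across pairs, which biases the
    class-mean intraclass correlation slightly downward (most visibly for the
    large unrelated class); on disjoint pairs the estimator is unbiased.
    """
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    keep = []
    for i in rng.permutation(len(pairs)):
        a, b = pairs.iloc[int(i)][["id_a", "id_b"]]
        if a in used or b in used:
            continue
        used.update((a, b))
        keep.append(int(i))
    return pairs.iloc[sorted(keep)].reset_index(drop=True)


def icc(values: np.ndarray) -> float:
    """One-way ANOVA intraclass correlation of paired values.

    ``values`` is a (n_pairs, 2) array; pairs with any missing member are
    dropped. Returns (MS_B - MS_W) / (MS_B + MS_W); if all values are
    identical both mean squares are zero and 0.0 is returned with a warning.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("values must be an (n_pairs, 2) array")
    arr = arr[~np.isnan(arr).any(axis=1)]
    k = arr.shape[0]
    if k < 2:
        raise ValueError("icc requires at least 2 complete pairs")
    grand = arr.mean()
    pair_means = arr.mean(axis=1)
    ms_b = 2.0 * np.sum((pair_means - grand) ** 2) / (k - 1)
    ms_w = np.sum((arr - pair_means[:, None]) ** 2) / k
    denom = ms_b + ms_w
    if denom == 0.0:
        logger.warning("icc undefined for identical values; returning 0")
        return 0.0
    return float((ms_b - ms_w) / denom)


def _icc_per_probe(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorised per-probe ICC for one relationship class.

    ``A`` and ``B`` are (n_probes, n_pairs) matrices of the two pair members'
    values; probes with fewer than 2 complete pairs give NaN.
    """
    complete = ~(np.isnan(A) | np.isnan(B))
    k = complete.sum(axis=1).astype(float)
    Az = np.where(complete, A, 0.0)
    Bz = np.where(complete, B, 0.0)
    tot = Az + Bz
    grand = tot.sum(axis=1) / np.maximum(2.0 * k, 1.0)
    pm = tot / 2.0  # pair means (garbage where incomplete; masked below)
    ss_b = np.where(complete, (pm - grand[:, None]) ** 2, 0.0).sum(axis=1)
    ms_b = 2.0 * ss_b / np.maximum(k - 1.0, 1.0)
    ss_w = np.where(complete, (Az - pm) ** 2 + (Bz - pm) ** 2, 0.0).sum(axis=1)
    ms_w = ss_w / np.maximum(k, 1.0)
    denom = ms_b + ms_w
    out = np.where(denom > 0, (ms_b - ms_w) / np.where(denom > 0, denom, 1.0), 0.0)
    out[k < 2] = np.nan
    return out


def correlation_table(
    resid: ResidualMatrix | pd.DataFrame,
    pairs: pd.DataFrame,
    chunk_size: int = 200,
) -> pd.DataFrame:
    """Average per-probe intraclass correlation for each relationship class.

    Computes the ICC probe by probe within each class, then averages across
    probes (unweighted). Probes with fewer than 2 complete pairs in a class
    are skipped for that class. Parent-offspring pairs additionally appear
    split into mother-/father-offspring rows. Probes are processed in chunks
    to bound memory for the large unrelated-pair class.
    """
    values = resid.values if isinstance(resid, ResidualMatrix) else resid
    sample_pos = {s: i for i, s in enumerate(values.columns)}
    missing = set(pairs["id_a"]) | set(pairs["id_b"]) - set(sample_pos)
    missing -= set(sample_pos)
    if missing:
        raise ValueError(f"pairs reference samples absent from the matrix: {sorted(missing)[:5]}")
    arr = values.to_numpy(float)
    n_probes = arr.shape[0]

    class_rows = []
    groups: list[tuple[str, pd.DataFrame]] = [
        (cls, grp) for cls, grp in pairs.groupby("relationship", sort=False)
    ]
    po = pairs[pairs["relationship"] == "parent_offspring"]
    for sub in ("mother_offspring", "father_offspring"):
        grp = po[po["subclass"] == sub]
        if len(grp):
            groups.append((sub, grp))

    order = ["MZ", "DZ", "sibling", "parent_offspring", "mother_offspring",
             "father_offspring", "spouse", "unrelated"]
    groups.sort(key=lambda item: order.index(item[0]) if item[0] in order else 99)

    for cls, grp in groups:
        ia = np.array([sample_pos[s] for s in grp["id_a"]])
        ib = np.array([sample_pos[s] for s in grp["id_b"]])
        # Bound the probes-x-pairs workspace at ~10M entries per chunk.
        chunk = min(chunk_size, max(1, 10_000_000 // max(len(grp), 1)))
        iccs = np.empty(n_probes)
        for start in range(0, n_probes, chunk):
            sl = slice(start, min(start + chunk, n_probes))
            iccs[sl] = _icc_per_probe(arr[sl][:, ia], arr[sl][:, ib])
        n_skipped = int(np.isnan(iccs).sum())
        if n_skipped:
            logger.info("%s: %d probes skipped (<2 complete pairs)", cls, n_skipped)
        share = float(grp["expected_share"].iloc[0])
        n_used = n_probes - n_skipped
        class_rows.append(
            {
                "relationship": cls,
                "n_pairs": len(grp),
                "mean_correlation": float(np.nanmean(iccs)),
                # Monte-Carlo standard error of the across-probe mean.
                "se_correlation": float(np.nanstd(iccs) / np.sqrt(max(n_used, 1))),
                "expected": EXPECTED_LABEL[share],
                "expected_share": share,
                "n_probes_used": n_used,
            }
        )
    return pd.DataFrame(class_rows)
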