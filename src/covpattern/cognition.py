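"""Composite cognitive domain z-scores from a neuropsychological battery.

Raw test scores are standardized to a healthy-control reference group
(z = (x - mean_HC) / sd_HC, sample SD), sign-aligned so that higher always
means better performance, averaged within each of four cognitive domains
(memory, attention, executive, visuospatial) to form composite scores, and
averaged across domains to form a global cognition score.  By construction
the reference-group mean of every composite is zero.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOMAINS = ("memory", "attention", "executive", "visuospatial")

# Default battery: a VAChT-PET cognition study battery with each test
# assigned to exactly one domain.  Editable by passing an explicit map.
DEFAULT_DOMAIN_MAP: dict[str, str] = {
    "VAT": "memory",
    "MoCA_MIS": "memory",
    "SDMT": "attention",
    "TMT_A": "attention",
    "Stroop_B": "attention",
    "Stroop_C_B": "executive",
    "TMT_B": "executive",
    "letter_fluency": "executive",
    "VOSP_cube": "visuospatial",
    "TEA_map_search": "visuospatial",
    "JOLO": "visuospatial",
}

# Timed endpoints where a higher raw score means worse performance; their
# z-scores are multiplied by -1.  This is an editable assumption: which
# endpoints need inversion depends on the local scoring convention.
DEFAULT_INVERTED: frozenset[str] = frozenset(
    {"TMT_A", "TMT_B", "Stroop_B", "Stroop_C_B"}
)


def validate_table(
    table: pd.DataFrame, domain_map: Mapping[str, str]
) -> list[str]:
    """Check table invariants; return warning messages (non-fatal issues).

    Raises ``ValueError`` on duplicated (subject, test) pairs, unmapped
    tests, or a domain with no mapped test.  A domain covered by fewer than
    two tests is allowed but recorded as a warning (battery-design
    recommendation, not a scoring rule).
    """
    required = {"subject_id", "test_id", "raw_score"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"cognition table missing columns: {sorted(missing_cols)}")
    dup = table.duplicated(subset=["subject_id", "test_id"])
    if dup.any():
        pairs = table.loc[dup, ["subject_id", "test_id"]].values.tolist()
        raise ValueError(f"duplicated (subject, test) pairs: {pairs[:5]}")
    unmapped = set(table["test_id"]) - set(domain_map)
    if unmapped:
        raise ValueError(f"tests not in the domain map: {sorted(unmapped)}")
    bad_domains = set(domain_map.values()) - set(DOMAINS)
    if bad_domains:
        raise ValueError(f"unknown domains in map: {sorted(bad_domains)}")

    warnings: list[str] = []
    tests_present = set(table["test_id"])
    for domain in DOMAINS:
        n = sum(1 for t in tests_present if domain_map[t] == domain)
        if n == 0:
            raise ValueError(f"domain '{domain}' has no mapped test in the table")
        if n < 2:
            msg = f"domain '{domain}' covered by a single test"
            warnings.append(msg)
            logger.warning(msg)
    return warnings


def zscore_tests(
    table: pd.DataFrame,
    reference_ids: Iterable,
    inverted: Iterable[str] = DEFAULT_INVERTED,
) -> pd.DataFrame:
    """Standardize each test to the reference (control) group.

    z = (raw - mean_ref) / sd_ref with sample SD (ddof=1), then multiplied
    by -1 for tests in ``inverted`` so that higher z = better performance.

    Parameters
    ----------
    table
        Long-format frame with columns subject_id, test_id, raw_score.
    reference_ids
        Subjects whose scores define the standardization (healthy controls).
    inverted
        Test ids whose sign is flipped after standardization.

    Returns
    -------
    Copy of ``table`` with a ``z`` column added.
    """
    reference_ids = set(reference_ids)
    if not reference_ids:
        raise ValueError("reference_ids must be non-empty")
    inverted = set(inverted)

    out = table.copy()
    out["z"] = np.nan
    n_ref_subjects = len(reference_ids)
    for test_id, grp in table.groupby("test_id", sort=False):
        ref = grp[grp["subject_id"].isin(reference_ids)]["raw_score"]
        if len(ref) < 2:
            raise ValueError(
                f"test '{test_id}': needs >= 2 reference observations, got {len(ref)}"
            )
        if len(ref) < n_ref_subjects:
            logger.info(
                "test '%s': reference statistics from %d of %d reference subjects",
                test_id, len(ref), n_ref_subjects,
            )
        mean_ref = ref.mean()
        sd_ref = ref.std(ddof=1)
        if not np.isfinite(sd_ref) or sd_ref == 0:
            raise ValueError(f"test '{test_id}': zero reference-group SD")
        z = (grp["raw_score"] - mean_ref) / sd_ref
        if test_id in inverted:
            z = -z
        out.loc[grp.index, "z"] = z
    return out


def composite_scores(
    ztable: pd.DataFrame, domain_map: Mapping[str, str] = DEFAULT_DOMAIN_MAP
) -> pd.DataFrame:
    """Average per-test z-scores into domain composites and a global score.

    A subject's domain composite is the mean of their available test
    z-scores in that domain (no imputation); a domain with no observed test
    is NaN for that subject.  The global score is the mean of the four
    domain composites and is defined only when all four are.

    Returns a wide frame indexed by subject_id with columns
    memory, attention, executive, visuospatial, global.
    """
    if "z" not in ztable.columns:
        raise ValueError("ztable must carry a 'z' column (run zscore_tests first)")
    t = ztable.copy()
    t["domain"] = t["test_id"].map(dict(domain_map))
    if t["domain"].isna().any():
        bad = sorted(t.loc[t["domain"].isna(), "test_id"].unique())
        raise ValueError(f"tests not in the domain map: {bad}")

    wide = t.pivot_table(index="subject_id", columns="domain", values="z",
                         aggfunc="mean")
    wide = wide.reindex(index=pd.unique(t["subject_id"]), columns=list(DOMAINS))
    if wide.isna().all(axis=1).any():
        bad = wide.index[wide.isna().all(axis=1)].tolist()
        raise ValueError(f"subjects with no test in any domain: {bad}")
    # global = mean of the four composites, NaN unless all four defined
    wide["global"] = wide[list(DOMAINS)].mean(axis=1, skipna=False)
    wide.columns.name = None
    return wide
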