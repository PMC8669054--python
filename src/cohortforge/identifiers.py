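"""Canonicalization of MRNs and accession numbers.

Hospital registries and PACS databases frequently disagree on identifier
formatting: one system drops the leading zeros of a fixed-width medical
record number (MRN) on export, another prepends a legacy prefix to
accession numbers minted before an EMR migration.  Record linkage between
a research registry and a PACS index is only possible once both sides are
reduced to a single canonical form.

Rules are data, not code: each site carries a :class:`SiteRuleSet`
(zero-pad width for MRNs, a literal accession prefix to strip), so adding
a hospital with a new convention requires only configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Tuple

import pandas as pd

__all__ = [
    "SiteRuleSet",
    "IdentifierError",
    "normalize_mrn",
    "normalize_accession",
    "normalize_cohort",
    "DEFAULT_SITE_RULES",
]


class IdentifierError(ValueError):
    """Raised for empty or unusable identifier values."""


@dataclass(frozen=True)
class SiteRuleSet:
    """Per-site identifier conventions.

    Parameters
    ----------
    site :
        Site code this rule set applies to.
    mrn_pad_width :
        Left-pad MRNs with zeros up to this width; ``0`` disables padding.
    acc_strip_prefix :
        Literal prefix removed once from the left of an accession;
        empty string disables stripping.
    """

    site: str
    mrn_pad_width: int = 0
    acc_strip_prefix: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.mrn_pad_width <= 16:
            raise ValueError(f"mrn_pad_width must be in [0, 16], got {self.mrn_pad_width}")


#: Replica conventions: site A pads MRNs to 8 digits and strips a legacy
#: leading "A" from pre-migration accessions; the other sites are clean.
DEFAULT_SITE_RULES: Mapping[str, SiteRuleSet] = {
    "site_a": SiteRuleSet("site_a", mrn_pad_width=8, acc_strip_prefix="A"),
    "site_b": SiteRuleSet("site_b"),
    "site_c": SiteRuleSet("site_c"),
}


def normalize_mrn(mrn: str, rules: SiteRuleSet) -> str:
    """Return the canonical (zero-padded) form of an MRN.

    Shorter-than-width values are left-padded with zeros; values already at
    or beyond the pad width pass through unchanged.  Non-numeric MRNs are
    padded as-is (no digit check is imposed).
    """
    value = str(mrn).strip()
    if not value:
        raise IdentifierError("empty MRN")
    if rules.mrn_pad_width and len(value) < rules.mrn_pad_width:
        value = value.rjust(rules.mrn_pad_width, "0")
    return value


def normalize_accession(acc: str, rules: SiteRuleSet) -> str:
    """Return the canonical accession: the site prefix stripped at most once."""
    value = str(acc).strip()
    if not value:
        raise IdentifierError("empty accession")
    prefix = rules.acc_strip_prefix
    if prefix and value.startswith(prefix):
        value = value[len(prefix):]
        if not value:
            raise IdentifierError(f"accession was only the prefix {prefix!r}")
    return value


def normalize_cohort(
    records: pd.DataFrame,
    site_rules: Mapping[str, SiteRuleSet] = DEFAULT_SITE_RULES,
) -> Tuple[pd.DataFrame, int]:
    """Canonicalize identifiers for a cohort, keeping raw values for audit.

    Adds ``patient_id_canonical``, ``accession_canonical``, ``reformatted``
    (True where either canonical field differs from its raw counterpart) and
    ``mrn_non_numeric`` (audit flag) columns.  Sites without an explicit rule
    set get identity rules.

    Returns
    -------
    (records, n_reformatted) :
        The augmented frame (same row count and order) and the number of
        records whose MRN or accession changed under normalization.
    """
    out = records.copy()
    identity = SiteRuleSet("_default")

    def _rules(site: str) -> SiteRuleSet:
        return site_rules.get(site, identity)

    mrn_canon = []
    acc_canon = []
    non_numeric = []
    for site, mrn, acc in zip(out["hospital"], out["patient_id"], out["accession"]):
        r = _rules(site)
        mrn_canon.append(normalize_mrn(mrn, r))
        acc_canon.append(normalize_accession(acc, r))
        non_numeric.append(not str(mrn).strip().isdigit())
    out["patient_id_canonical"] = mrn_canon
    out["accession_canonical"] = acc_canon
    out["mrn_non_numeric"] = non_numeric
    out["reformatted"] = (
        out["patient_id_canonical"].ne(out["patient_id"].astype(str).str.strip())
        | out["accession_canonical"].ne(out["accession"].astype(str).str.strip())
    )
    return out, int(out["reformatted"].sum())
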