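"""Published marginal impairment counts used as calibration targets.

These are the per-domain impaired/assessed counts reported for a prospective
cohort of 56 extremely-preterm (EPT, <28 gestational weeks) and 37 term-born
children assessed at six years of age — the study design this package
emulates.  They serve two purposes: worked-example inputs for the 2×2 odds
ratio (the published unadjusted ORs are reproducible from these counts
alone), and marginal prevalence targets for calibrating the synthetic
cohort generator.

Denominators vary by domain because of non-systematic missing assessments.
"""

from __future__ import annotations

from .registry import DEFAULT_REGISTRY

#: domain -> ((ept_impaired, ept_assessed), (term_impaired, term_assessed))
REFERENCE_COUNTS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "MND": ((36, 56), (10, 36)),
    "MD": ((13, 50), (1, 36)),
    "AC": ((3, 50), (1, 36)),
    "BAL": ((6, 50), (0, 36)),
    "MFP": ((10, 49), (0, 33)),
    "FI": ((24, 49), (10, 33)),
    "DC": ((14, 49), (1, 33)),
    "MAc": ((15, 49), (1, 33)),
    "PPr": ((16, 49), (4, 33)),
    "BMC": ((19, 49), (3, 33)),
    "AuAttn": ((12, 46), (1, 33)),
    "VisAttn": ((6, 45), (1, 34)),
    "MemoD": ((16, 45), (7, 34)),
    "MemoF": ((9, 44), (5, 34)),
    "MemoN": ((12, 48), (2, 34)),
    "ImHP": ((19, 44), (7, 34)),
    "Arrows": ((8, 47), (1, 34)),
    "BloC": ((9, 46), (1, 34)),
    "DeCo": ((33, 49), (12, 34)),
    "GeoP": ((10, 45), (2, 34)),
}

assert set(REFERENCE_COUNTS) == set(DEFAULT_REGISTRY.abbreviations)

#: Cohort sizes of the reference study.
N_EPT = 56
N_TERM = 37


def reference_rates(continuity: float = 0.5) -> dict[str, tuple[float, float]]:
    """Per-domain (EPT, term) impairment rates from the published counts.

    Zero counts are replaced by ``continuity``/N (a half-count by default)
    so that every rate lies in (0, 1) and is usable as a calibration
    target; the resulting target (≈0.015) is indistinguishable from 0% at
    the cohort sizes involved.
    """
    rates = {}
    for domain, ((ke, ne), (kt, nt)) in REFERENCE_COUNTS.items():
        ept = (ke if ke > 0 else continuity) / ne
        term = (kt if kt > 0 else continuity) / nt
        rates[domain] = (ept, term)
    return rates


def reference_table_2x2(domain: str) -> tuple[int, int, int, int]:
    """2×2 cells (a, b, c, d) for one domain.

    a = EPT impaired, b = EPT unimpaired, c = term impaired,
    d = term unimpaired, using each group's assessed denominator.
    """
    (ke, ne), (kt, nt) = REFERENCE_COUNTS[domain]
    return ke, ne - ke, kt, nt - kt
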