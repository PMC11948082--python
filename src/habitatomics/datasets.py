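"""Published summary data of the multicenter neoadjuvant-treatment study
whose analysis pipeline this package re-implements.

Only aggregate counts are available (the imaging and omics data are not
deposited); these tables serve as fixed reference inputs for cohort
bookkeeping and for configuring realistic synthetic cohorts.
"""

from __future__ import annotations

__all__ = ["PCR_COUNTS", "ENROLLMENT", "pooled_pcr_rate"]

#: pCR counts per cohort: {cohort: (n_pCR, n_total)}.  Four cohorts of the
#: 12-center study: training, external validation, neoadjuvant
#: immunotherapy, and multi-omics.
PCR_COUNTS = {
    "training": (167, 431),
    "external_validation": (590, 1595),
    "immunotherapy": (55, 88),
    "multi_omics": (92, 165),
}

ENROLLMENT = sum(n for _, n in PCR_COUNTS.values())


def pooled_pcr_rate() -> float:
    """Pooled pCR proportion across all cohorts, in percent."""
    achieved = sum(k for k, _ in PCR_COUNTS.values())
    return 100.0 * achieved / ENROLLMENT
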