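"""Shared fixtures and hypothesis settings."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_set():
    """A small indel-free synthetic set with one engineered primer pair."""
    import hcbprimer as h
    from hcbprimer.synthetic import (
        DEFAULT_FORWARD_MOTIF,
        DEFAULT_REVERSE_PRIMER,
        PrimerSite,
        SynthConfig,
    )

    cfg = SynthConfig(
        n_genera=3,
        seqs_per_genus=10,
        seq_length=900,
        indel_rate=0.0,
        seed=42,
        primer_sites=(
            PrimerSite(DEFAULT_FORWARD_MOTIF, 151),
            PrimerSite(h.reverse_complement(DEFAULT_REVERSE_PRIMER), 716),
        ),
    )
    records, truth = h.generate_reference_set(cfg)
    return cfg, records, truth
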