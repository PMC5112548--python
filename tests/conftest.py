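import pytest

from wrkykit.motif_scan import (
    HeptapeptideHit,
    Terminal,
    VariantClass,
    WRKYDomainHit,
    ZincFingerHit,
    ZincFingerType,
    render_zf_pattern,
)


def make_wrky_hit(protein_id: str, start: int, end: int = None) -> WRKYDomainHit:
    """Minimal well-formed domain hit for classifier tests."""
    if end is None:
        end = start + 52
    hepta_start = start + 10
    zf_positions = (hepta_start + 10, hepta_start + 15, hepta_start + 39, hepta_start + 41)
    return WRKYDomainHit(
        protein_id=protein_id,
        start=start,
        end=end,
        heptapeptide=HeptapeptideHit(
            start=hepta_start,
            tetramer="WRKY",
            tail="GQK",
            variant_class=VariantClass.CANONICAL,
        ),
        zinc_finger=ZincFingerHit(
            positions=zf_positions,
            zf_type=ZincFingerType.C2H2,
            spacer_pattern=render_zf_pattern((4, 23, 1), ZincFingerType.C2H2),
        ),
        terminal=Terminal.SINGLE_C,
    )


@pytest.fixture
def wrky_hit_factory():
    return make_wrky_hit
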