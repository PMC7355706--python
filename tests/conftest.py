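import pytest

from gisim.io import drug_preset
from gisim.transit import ConditionConfig, PiecewiseProfile, TransitParameters


@pytest.fixture(scope="session")
def loratadine():
    return drug_preset("loratadine")


@pytest.fixture(scope="session")
def recovery_water():
    """Water-like recovery scenario: supersaturating intestinal chambers.

    Identifiable free set: z_s (gastric dissolution), k_pre_d, k_pre_j
    (precipitation of the supersaturated excess). Intestinal dissolution and
    the particle-transfer fraction carry no concentration signal here because
    both intestinal chambers sit at or above saturation throughout.
    """
    from gisim.synthetic import condition_preset

    cond, _ = condition_preset(1)
    truth = TransitParameters(
        z_s=1.5e-11, z_d=4e-11, z_j=1e-11, frac=0.5, k_pre_d=0.05, k_pre_j=0.01
    )
    return cond, truth


@pytest.fixture(scope="session")
def recovery_acid_dip():
    """Acid-load recovery scenario: transient intestinal pH dips.

    The dips raise intestinal solubility so transferred solids actually
    dissolve, making z_d, z_j and the transfer fraction identifiable;
    precipitation rates are set effectively to zero (no supersaturation
    persists), matching the boundary-recovery regime.
    """
    cond = ConditionConfig(
        label="recovery_acid_dip",
        t_half_gastric=15.0,
        gastric_ph_profile=PiecewiseProfile.constant(2.48),
        duodenal_ph_profile=PiecewiseProfile.from_points(
            [(0, 6.5), (7.5, 3.0), (45, 6.5), (60, 6.5)]
        ),
        jejunal_ph_profile=PiecewiseProfile.from_points(
            [(0, 6.5), (12, 3.5), (55, 6.5), (60, 6.5)]
        ),
    )
    truth = TransitParameters(
        z_s=5e-12, z_d=4e-10, z_j=2.5e-10, frac=0.6, k_pre_d=1e-5, k_pre_j=1e-5
    )
    return cond, truth
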