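import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from terpenebudget.datamodel import NSCProfile, TreeRecord
from terpenebudget.simulate import GeneratorParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The canonical 46-tree synthetic cohort (seed 0)."""
    return generate_cohort(GeneratorParams(seed=0))


@pytest.fixture(scope="session")
def noiseless_params():
    """All noise sd's zero and no girdle loss: every tree sits on its mean."""
    return GeneratorParams(
        seed=0,
        constitutive_mst_sd=0.0,
        mst_noise_sd=0.0,
        girdle_rel_noise_sd=0.0,
        sugar_pre_sd=0.0,
        starch_pre_watered=(0.3, 0.0),
        starch_pre_drought=(0.03, 0.0),
        osmolality_sd=0.0,
        chamber_temp_sd=0.0,
        girdle_loss_anchors=((-0.31, 0.0), (-3.61, 0.0)),
        depletion_pct={"C": (0.0, 0.0), "G": (52.0, 0.0),
                       "I": (76.0, 0.0), "I+G": (89.0, 0.0)},
        n_missing_post=0,
    )


def make_tree(tree_id="T001", *, psi_pd=-0.5, girdled=False, inoculated=False,
              water_group="watered", mst_pre=20.0, mst_post=30.0,
              nsc_pre=None, nsc_post=None, **kw):
    """Hand-built TreeRecord with sensible defaults for unit tests."""
    stratum = "well_watered" if water_group == "watered" else "mild"
    return TreeRecord(
        tree_id=tree_id,
        water_group=water_group,
        drought_stratum=kw.pop("drought_stratum", stratum),
        girdled=girdled,
        inoculated=inoculated,
        psi_pd=psi_pd,
        mst_pre=mst_pre,
        mst_post=mst_post,
        nsc_pre=nsc_pre or NSCProfile(0.3, 2.7, 1.2, 1.2),
        nsc_post=nsc_post,
        **kw,
    )
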