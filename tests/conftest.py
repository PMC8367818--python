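import numpy as np
import pytest

from taxolminer import syn_data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_study():
    """Expression study with planted tissue, cell-line and MeJA structure.

    One anchor plus ten true coregulation partners follow the latent MeJA
    trajectory; fifty background genes plus the pathway genes carry a
    4-fold HC-over-LC effect; the pathway genes are root/bark-elevated.
    """
    anchors = ("g00001",)
    partners = tuple(f"g{i:05d}" for i in range(10, 20))
    pathway = set(partners) | set(anchors)
    hc_planted = {f"g{i:05d}": 2.0 for i in range(30, 80)}
    design = syn_data.ExprDesign(
        n_genes=2000,
        anchor_ids=anchors,
        partner_ids=partners,
        hc_lc_log2_effect={**hc_planted, **{g: 2.0 for g in pathway}},
        tissue_log2_effects={g: 2.0 for g in pathway},
        seed=42,
    )
    study = syn_data.simulate_expression(design)
    return {
        "study": study,
        "design": design,
        "anchors": anchors,
        "partners": partners,
        "hc_planted": set(hc_planted) | pathway,
    }


@pytest.fixture(scope="session")
def null_study():
    """Expression study with no planted effects at all."""
    return syn_data.simulate_expression(
        syn_data.ExprDesign(n_genes=2000, anchor_ids=(), partner_ids=(), seed=99)
    )
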