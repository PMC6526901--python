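"""Shared fixtures: small trees, simulated alignments, and cached fits."""

import numpy as np
import pytest

import imprintsel as ims
from imprintsel.codon_model import FitOptions, fit_model

SIX_TAXON_NEWICK = "((a:0.15,b:0.2):0.1,(c:0.25,d:0.1):0.12,(e:0.3,f:0.2):0.08);"


@pytest.fixture(scope="session")
def tree6():
    return ims.PhyloTree.from_newick(SIX_TAXON_NEWICK)


@pytest.fixture(scope="session")
def m0_alignment(tree6):
    """300-codon alignment simulated under a single omega = 0.5 class."""
    params = ims.CodonModelParams(2.0, [ims.SiteClass(0.5, 1.0)])
    aln, truth = ims.simulate_codon_alignment(tree6, params, 300, seed=11)
    return aln, truth


@pytest.fixture(scope="session")
def ps_site_data(tree6):
    """150-codon alignment with 10% of sites at omega = 6 (site-level PS)."""
    classes = [
        ims.SiteClass(0.1, 0.7),
        ims.SiteClass(1.0, 0.2),
        ims.SiteClass(6.0, 0.1, positive=True),
    ]
    params = ims.CodonModelParams(2.0, classes)
    aln, truth = ims.simulate_codon_alignment(tree6, params, 150, seed=3)
    return aln, truth


@pytest.fixture(scope="session")
def ps_site_m0(ps_site_data, tree6):
    aln, _ = ps_site_data
    return fit_model((aln, tree6), "M0", FitOptions(starts=1))


@pytest.fixture(scope="session")
def m8_fit_with_signal(ps_site_data, tree6, ps_site_m0):
    aln, _ = ps_site_data
    opts = FitOptions(starts=2, base_fit=ps_site_m0)
    return fit_model((aln, tree6), "M8", opts)


@pytest.fixture(scope="session")
def branch_site_data():
    """Foreground-marked tree plus data with positive selection on it."""
    tree = ims.PhyloTree.from_newick(
        "((a#1:0.3,b:0.2):0.1,(c:0.25,d:0.1):0.12,(e:0.3,f:0.2):0.08);"
    )
    classes = [
        ims.SiteClass(0.0, 0.55),
        ims.SiteClass(1.0, 0.25),
        ims.SiteClass(0.0, 0.12, 5.0, positive=True),
        ims.SiteClass(1.0, 0.08, 5.0, positive=True),
    ]
    params = ims.CodonModelParams(2.0, classes)
    aln, truth = ims.simulate_codon_alignment(tree, params, 200, seed=0)
    return aln, tree, truth
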