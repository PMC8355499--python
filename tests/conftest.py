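import pandas as pd
import pytest

import te_longsel as tl


@pytest.fixture
def basic_design() -> tl.StudyDesign:
    """Balanced 3 + 3 design without diets."""
    return tl.make_design("StudyA", 3, 3, ne_control=300, ne_selected=300,
                          gen_control=100, gen_selected=58)


@pytest.fixture
def diet_design() -> tl.StudyDesign:
    """2 + 2 replicates in each of three larval diets."""
    return tl.make_design("StudyD", 2, 2, diets=["low", "medium", "high"],
                          ne_control=250, ne_selected=250,
                          gen_control=58, gen_selected=58)


@pytest.fixture
def small_synth(basic_design):
    """A small seeded synthetic study shared by several test modules."""
    cfg = tl.SynthConfig(n_families=30, n_s_gt_c=4, n_c_gt_s=2, delta=1.0,
                         n_positions=40, max_sites_per_family=40, seed=11)
    hier, truths, profile, sites = tl.generate_study(cfg, basic_design)
    return {
        "config": cfg, "design": basic_design, "hierarchy": hier,
        "truths": truths, "profile": profile, "sites": sites,
    }


def make_profile(values_by_family, samples, hierarchy=None):
    """Build a CoverageProfile from {family: {sample: [per-position values]}}."""
    rows = []
    for fam, by_sample in values_by_family.items():
        for sample in samples:
            vals = by_sample[sample]
            for pos, v in enumerate(vals, start=1):
                rows.append({"family": fam, "sample": sample,
                             "pos": pos, "insertions": float(v)})
    return tl.CoverageProfile(data=pd.DataFrame(rows),
                              hierarchy=hierarchy or {})
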