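import pytest

import coloctk as ct


@pytest.fixture(scope="session")
def default_spec():
    return ct.FixtureSpec()


@pytest.fixture(scope="session")
def default_collection(default_spec):
    return ct.make_profile_collection(default_spec)


@pytest.fixture(scope="session")
def outlier_spec():
    # sparse profiles: a random profile rarely touches a replicate, so the
    # planted partition (8 jittered copies + 3 random members) is clean
    return ct.FixtureSpec(
        n_profiles=0, replicates=8, n_outliers=3,
        intervals_per_profile=20, jitter=100, seed=11,
    )


@pytest.fixture(scope="session")
def disk_collection(tmp_path_factory):
    """A small collection written to disk (BED files + manifest + hierarchy)."""
    out = tmp_path_factory.mktemp("coll")
    spec = ct.FixtureSpec(n_profiles=6, intervals_per_profile=50, seed=3)
    coll = ct.make_profile_collection(spec, outdir=out)
    return spec, coll
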