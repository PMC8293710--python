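import pytest

from dmdkit import fixtures as fx


@pytest.fixture()
def scheme():
    return fx.make_example_scheme()


@pytest.fixture()
def clean_bundle(scheme, tmp_path):
    """Clean filled metadata with matching toy data files on disk."""
    meta, expected = fx.make_filled_metadata(scheme, n_species=3, n_data_files=3)
    data_dir = tmp_path / "data"
    fx.make_toy_datafiles(meta, data_dir)
    assert expected == []
    return meta, data_dir
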