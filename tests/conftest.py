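import pytest

from ntcsim import optics

# the five measurement configurations: stock path plus the two movable-lens
# endpoints of each non-telecentric family
FIVE_CONFIGS = [
    ("DL", None),
    ("nTC1", 100.0),
    ("nTC1", 5.0),
    ("nTC2", 100.0),
    ("nTC2", 5.0),
]


@pytest.fixture(scope="session")
def dl_config():
    return optics.make_config("DL")


@pytest.fixture(scope="session")
def ntc1_config():
    return optics.make_config("nTC1", 100.0)


@pytest.fixture(scope="session", params=FIVE_CONFIGS, ids=lambda p: f"{p[0]}@{p[1]}")
def any_config(request):
    preset, d = request.param
    return optics.make_config(preset, d)
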