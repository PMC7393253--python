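import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def project(tmp_path):
    """A fresh empty project."""
    import expipe

    return expipe.create_project(tmp_path / "proj")


@pytest.fixture
def action(project):
    return project.create_action("ecephys-1")


@pytest.fixture
def isolated_config(tmp_path, monkeypatch):
    """Point the global CLI config at a throwaway file."""
    path = tmp_path / "config.yaml"
    monkeypatch.setenv("EXPIPE_CONFIG_PATH", str(path))
    return path
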