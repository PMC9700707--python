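import numpy as np
import pytest

from mirpanel import GenePanel, ToolRegistry, datasets


@pytest.fixture(scope="session")
def panel() -> GenePanel:
    return datasets.athero_panel()


@pytest.fixture(scope="session")
def registry() -> ToolRegistry:
    return ToolRegistry.default(30)


@pytest.fixture(scope="session")
def small_registry() -> ToolRegistry:
    return ToolRegistry.default(10)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
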