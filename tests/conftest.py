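import numpy as np
import pytest

import myofiber as mf
from myofiber.config import MESH_SECTION


@pytest.fixture(scope="session")
def slab_hex():
    return mf.make_slab(mf.SlabSpec())


@pytest.fixture(scope="session")
def slab_tet():
    return mf.make_slab(mf.SlabSpec(element_type="Tet"))


@pytest.fixture(scope="session")
def shell():
    return mf.make_shell(mf.ShellSpec())


@pytest.fixture(scope="session")
def la_shell():
    return mf.make_la_shell()


@pytest.fixture(scope="session")
def lv():
    return mf.make_lv(mf.EllipsoidLVSpec())


@pytest.fixture(scope="session")
def lv_complete():
    return mf.make_lv_complete_shell()


def config_for(geometry: str, element_type: str = "Tet", **geo_overrides) -> mf.LDRBMConfig:
    cfg = mf.LDRBMConfig.defaults(geometry)
    cfg.set(MESH_SECTION, "Element type", element_type)
    for name, value in geo_overrides.items():
        cfg.set(geometry, name, value)
    return cfg


@pytest.fixture()
def unit_tet_msh_v22(tmp_path):
    """Minimal hand-written MSH 2.2: 4 nodes, 1 tet, 4 labeled triangles."""
    text = """$MeshFormat
2.2 0 8
$EndMeshFormat
$Nodes
4
1 0 0 0
2 1 0 0
3 0 1 0
4 0 0 1
$EndNodes
$Elements
5
1 2 2 11 1 1 3 2
2 2 2 12 2 1 2 4
3 2 2 13 3 1 4 3
4 2 2 14 4 2 3 4
5 4 2 1 1 1 2 3 4
$EndElements
"""
    p = tmp_path / "unit_tet.msh"
    p.write_text(text)
    return p
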