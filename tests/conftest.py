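import numpy as np
import pytest

import acroface as af


@pytest.fixture(scope="session")
def template():
    return af.default_template()


@pytest.fixture(scope="session")
def template_mesh():
    return af.default_template(with_mesh=True)


@pytest.fixture()
def template_scan(template):
    return af.FaceScan("tpl", "male", "control", dict(template.coords))


@pytest.fixture()
def template_scan_mesh(template_mesh):
    t = template_mesh
    return af.FaceScan(
        "tpl", "male", "control", dict(t.coords), t.mesh_vertices, t.mesh_faces
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation via QR."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
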