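import numpy as np
import pytest

from polypdet import nn as N


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def numeric_grad_check(build, tensors, eps=1e-3, tol=0.03, n_samples=4, seed=0):
    """Compare analytic gradients of ``build(*tensors)`` (a scalar) against
    central finite differences on a few randomly sampled entries."""
    out = build(*tensors)
    for t in tensors:
        t.grad = None
    out.backward()
    sampler = np.random.default_rng(seed)
    for t in tensors:
        flat = t.data.reshape(-1)
        grad = (t.grad if t.grad is not None else np.zeros_like(t.data)).reshape(-1)
        idx = sampler.choice(flat.size, min(n_samples, flat.size), replace=False)
        for j in idx:
            orig = flat[j]
            flat[j] = orig + eps
            lp = float(build(*tensors).data)
            flat[j] = orig - eps
            lm = float(build(*tensors).data)
            flat[j] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - grad[j]) <= tol * max(1.0, abs(num), abs(grad[j])), \
                f"gradient mismatch at {j}: numeric {num}, analytic {grad[j]}"


@pytest.fixture
def grad_check():
    return numeric_grad_check
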