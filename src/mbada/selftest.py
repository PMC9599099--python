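"""Installation self-test: the core mathematical guarantees, quickly.

Checks the properties everything else rests on — basis orthogonality,
full-order round-trip identity, SSIM self-identity, and constant-image
closure — on small built-in inputs.  Used by ``mbada selftest``.
"""

from __future__ import annotations

import numpy as np

from .attack import AttackConfig, attack_image
from .basis import build_basis
from .fixtures import FixtureSpec, generate
from .metrics import mean_ssim
from .transform import forward_moments, reconstruct

__all__ = ["run_selftest"]


def _gram_checks() -> list[tuple[str, bool, str]]:
    out = []
    for N in (4, 8, 16):
        b = build_basis(N, N - 1)
        G = b.values @ b.values.T
        off = np.abs(G - np.diag(np.diag(G))).max()
        diag_err = np.abs(np.diag(G) - b.norms).max()
        ok = off <= 1e-8 * b.norms.min() and diag_err <= 1e-10 * b.norms.max()
        out.append((f"orthogonality N={N} (full order)", ok,
                    f"max off-diagonal {off:.2e}"))
    b = build_basis(64, 63)
    G = b.values @ b.values.T
    pair = np.sqrt(np.outer(b.norms, b.norms))
    rel = (np.abs(G - np.diag(np.diag(G))) / pair).max()
    out.append(("orthogonality N=64 (pairwise relative)", rel <= 1e-12,
                f"max relative off-diagonal {rel:.2e}"))
    return out


def run_selftest(verbose: bool = True) -> bool:
    """Run all checks; print one line each; return True iff all pass."""
    checks = _gram_checks()

    rng = np.random.default_rng(20221013)
    f = rng.random((32, 32))
    err = np.abs(reconstruct(forward_moments(f, 31, 31)) - f).max()
    checks.append(("round-trip 32x32 (full order)", err <= 1e-8,
                   f"max abs error {err:.2e}"))

    img = generate(FixtureSpec(kind="random_smooth", height=32, width=32, seed=3))
    s = mean_ssim(img, img)
    checks.append(("SSIM self-identity", s == 1.0, f"mean SSIM {s!r}"))

    const = generate(FixtureSpec(kind="constant", height=16, width=16, value=0.5))
    ms = forward_moments(const, 3, 3)
    m00 = ms.moments[0, 0, 0]
    rest = np.abs(ms.moments[0]).sum() - abs(m00)
    res = attack_image(const, AttackConfig(order=0, output_encoding="float"))
    dev = np.abs(res.adversarial.pixels - const.pixels).max()
    ok = abs(m00 - 0.5) <= 1e-12 and rest <= 1e-10 and dev <= 1e-12
    checks.append(("constant-image closure (M00, order-0 attack)", ok,
                   f"M00 {m00:.12f}, residual {rest:.2e}, attack dev {dev:.2e}"))

    all_ok = all(ok for _, ok, _ in checks)
    if verbose:
        for name, ok, detail in checks:
            print(f"[{'PASS' if ok else 'FAIL'}] {name}: {detail}")
        print("selftest:", "all checks passed" if all_ok else "FAILURES present")
    return all_ok
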