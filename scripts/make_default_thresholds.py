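"""Regenerate the bundled per-size MJS hit thresholds.

Calibrates the 22 fragment-size thresholds (0.95 target precision) on a
fixed-seed synthetic bank and query set, using the bundled toy alphabet,
and writes src/safrag/data/default_mjs_thresholds.json.

Run from the repository root:  python scripts/make_default_thresholds.py
"""

import json
from pathlib import Path

import numpy as np

from safrag import (
    BankSpec,
    build_bank,
    build_chain,
    calibrate_protocol,
    load_default_model,
    posterior_profile,
    pseudo_predict,
)

SEED = 404
OUT = (
    Path(__file__).resolve().parents[1]
    / "src" / "safrag" / "data" / "default_mjs_thresholds.json"
)


def main() -> None:
    model = load_default_model()
    bank = build_bank(
        BankSpec(
            n_proteins=20, min_len=30, max_len=60, noise_sd=0.3,
            prediction_concentration=50.0, seed=SEED,
        ),
        model,
    )
    rng = np.random.default_rng(SEED + 1)
    queries = []
    for q in range(8):
        trace = build_chain(
            int(rng.integers(60, 80)), (0.4, 0.25, 0.2, 0.15), 0.3, rng, f"cal{q}"
        )
        profile = pseudo_predict(
            posterior_profile(trace, model), 50.0, seed=int(rng.integers(2**31))
        )
        queries.append((trace, profile))
    _, cfg, _ = calibrate_protocol(bank, queries, seed=SEED + 2)
    OUT.write_text(
        json.dumps({str(k): v for k, v in sorted(cfg.mjs_thresholds.items())}, indent=1)
    )
    print(f"wrote {OUT}")
    print(json.dumps(cfg.mjs_thresholds, indent=None))


if __name__ == "__main__":
    main()
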