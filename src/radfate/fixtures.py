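"""Deterministic toy inputs for tests, examples and quick starts."""

from __future__ import annotations

import hashlib
import json
import shutil
from pathlib import Path

from .compartments import assign_pathways
from .damage import generate_damage, write_damage_tsv
from .p53net import default_param_path

__all__ = ["generate_fixtures"]

_FIT_TEMPLATE = """\
# One row per radiation quality: complex-DSB fraction from damage
# simulation, slow fraction fitted from a repair curve, and the matched
# X-ray slow fraction from the same study.  Fill in and feed to
# radfate.compartments.read_fit_data_tsv / fit_exf_line.
label\tdsb_c_fraction\tf_slow\tf_slow_xray
example_xray\t0.05\t0.18\t0.18
example_helium\t0.25\t0.40\t0.18
example_carbon\t0.45\t0.55\t0.18
"""


def generate_fixtures(output_dir) -> dict[str, str]:
    """Write fixed-seed toy inputs; returns {filename: sha256}.

    Files: three small damage sets (pure fast, pure slow, mixed 60/40
    fast/slow by forced Bernoulli draw), the default p53 parameter
    file, and a fit-input template.  Fixed seeds make every file
    byte-identical across runs.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    damage = generate_damage(
        dose=0.5, dsb_yield=40.0, complex_fraction=0.1, hc_fraction=0.2, seed=1234
    )
    flavors = {
        "damage_pure_fast.tsv": 0.0,
        "damage_pure_slow.tsv": 1.0,
        "damage_mixed_40slow.tsv": 0.4,
    }
    for fname, f_slow in flavors.items():
        assigned = assign_pathways(damage, seed=99, forced_f_slow=f_slow)
        write_damage_tsv(assigned, out / fname)

    shutil.copy(default_param_path(), out / "p53_params.tsv")
    (out / "fit_template.tsv").write_text(_FIT_TEMPLATE)

    checksums = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir())
        if p.suffix == ".tsv"
    }
    (out / "MANIFEST.json").write_text(json.dumps(checksums, indent=2))
    return checksums
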