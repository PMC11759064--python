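"""Sticker lifetime extremes: Kelvin-Voigt gel vs Maxwell melt.

Runs the gel_vs_melt workflow at reduced scale: the same chains are
simulated un-cross-linked (transient contacts only) and irreversibly
cross-linked through their stickers.  The gel's G*(t) levels off at an
equilibrium plateau (Kelvin-Voigt solid); the melt's decays to zero
(Maxwell fluid).

Run:  python examples/gel_vs_melt.py            (~1 minute)
"""

import json
import tempfile
from pathlib import Path

from condrheo.workflows import run_workflow

out = Path(tempfile.mkdtemp(prefix="condrheo_"))
manifest = run_workflow("gel_vs_melt", out_dir=out, reduced=True, seed=3)

res = json.loads((out / "gel_vs_melt/classification.json").read_text())
fit = json.loads((out / "gel_vs_melt/fit_gel.json").read_text())
print(f"cross-links formed: {res['gel_links']} "
      f"(largest bonded component: {res['gel_largest_component']:.0%} of the network)")
print(f"melt classification: {res['melt']}")
print(f"gel  classification: {res['gel']}")
print(f"gel equilibrium plateau G0 = {fit['plateau']:.2f} p* "
      "(a frequency-independent G' floor; its zero-shear viscosity is infinite)")
print(f"artifacts + manifest in {out}/gel_vs_melt")
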