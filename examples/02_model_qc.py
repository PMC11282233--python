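"""Curation diagnostics on deliberately broken reconstructions.

Each bundled fixture carries exactly one defect class found in draft
genome-scale models: a thermodynamically infeasible cycle, a mass-imbalanced
reaction, an orphan metabolite, and a blocked branch.
"""

import commflux as cf

media = cf.Media("glucose", {"EX_glc": 10.0})

for name, model in cf.make_broken_fixtures().items():
    if name == "degenerate":
        media_used = cf.Media("substrate", {"EX_s": 10.0})
    else:
        media_used = media
    report = cf.qc_report(model, media_used)
    print(f"{name} ({model.id}):")
    print(f"  unbound (TIC members): {[r for r, _ in report.unbound]}")
    print(f"  imbalanced: {[(r, imb) for r, imb, _ in report.imbalanced]}")
    print(f"  dead ends: {report.dead_end}")
    print(f"  blocked: {report.blocked}")

# The TIC pair carries arbitrary flux with all uptakes closed; the bad
# fermentation drops one C2H4O2 unit (imbalance C:-2, H:-4, O:-2); the orphan
# metabolite is declared but never used; the ribose branch is blocked because
# the media supplies no ribose.
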