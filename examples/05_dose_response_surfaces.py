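"""TCP-BED-tumour-size response surfaces under a 3-fraction scenario.

Each model's surface is evaluated on a rectangular grid; models without a
size term are flat along the size axis.  Raw values are retained alongside
the conventional 50-100% display window.
"""

from sbrt_tcp import load_params, tcp_surface

params = load_params()
for model, horizon in (("liu", 2), ("klement", 2), ("ohri", 2),
                       ("gucken", 3), ("santiago", 3)):
    g = tcp_surface(model, params[model], n_fractions=3, horizon=horizon)
    flat = g.tcp.std(axis=0).max() < 1e-12
    print(f"{model:9s} {horizon}y: TCP range {g.tcp.min():.3f}-{g.tcp.max():.3f}"
          f"{'  (no size dependence)' if flat else ''}")
# steep, model-specific transitions along the BED axis are why the models
# disagree most visibly at intermediate doses
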