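"""Biologically effective dose for common lung-SBRT schedules.

Parses clinical shorthand, computes the LQ BED10 and the regrowth-corrected
BED used by the time-dependent probit model.
"""

from sbrt_tcp import compute_bed, compute_regrowth_bed, parse_schedule

for text in ("12.5 Gy×4", "10.0 Gy×5", "25 Gy×1", "7.5x8"):
    s = parse_schedule(text, elapsed_time_days=7.0)
    bed = compute_bed(s)
    bed_rg = compute_regrowth_bed(s, alpha_per_gy=0.3, t_p_days=3.0)
    print(f"{text:>10}: total {s.total_dose_gy:5.1f} Gy, BED10 {bed:6.1f} Gy, "
          f"regrowth-corrected {bed_rg:6.1f} Gy")

# BED10 > 100 Gy is the traditional local-control dose threshold; the
# regrowth correction subtracts ~5 Gy for a 7-day course (ln2/(alpha*T_p)*7).
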