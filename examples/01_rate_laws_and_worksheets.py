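"""Rate laws and derivation worksheets.

Evaluates the Hill-type synthesis/release laws at the documented pool sizes
and prints the worksheets that every steady-state pool and flux is derived
from (body composition, tissue cholesterol densities, the daily intestinal
flux budget).
"""

from cholsim import (
    ParameterSet,
    biliary_release_rate,
    bile_salt_synthesis_rate,
    hepatic_synthesis_rate,
    intestinal_synthesis_rate,
    worksheet_tables,
)

p = ParameterSet.default()

print("Rate laws at the documented 20-year-old male state:")
print(f"  intestinal synthesis at IC=3150 mg : "
      f"{intestinal_synthesis_rate(3150, p):7.1f} mg/day (budget ~49)")
print(f"  hepatic synthesis at HFC=60000 mg  : "
      f"{hepatic_synthesis_rate(60_000, p):7.1f} mg/day")
print(f"  biliary release at HFC=60000 mg    : "
      f"{biliary_release_rate(60_000, p):7.1f} mg/day (~1200 documented)")
print(f"  bile-salt synthesis (HFC/HBS)      : "
      f"{bile_salt_synthesis_rate(60_000, 400, p):7.1f} mg/day (~400 lost/day)")

print("\nDerivation worksheets (inputs and the numbers they fix):")
for name, table in worksheet_tables().items():
    print(f"\n--- {name} ---")
    print(table.to_string(index=False))
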