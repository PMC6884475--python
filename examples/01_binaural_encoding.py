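"""The deviation-to-sound conversion rule.

Maps lateral deviations to per-ear white-noise levels (dB re the maximum
tolerable level) and decodes them back.  On the lane centre both ears sit
at -50 dB; each metre of leftward drift raises the left ear and lowers the
right ear by 25 dB.
"""

from lanecue import BinauralLevel, decode, encode

print(f"{'deviation (m)':>14} {'left (dB)':>10} {'right (dB)':>11} {'decoded (m)':>12}")
for d in (-2.5, -1.0, -0.2, 0.0, 0.2, 1.0, 2.5):
    lev = encode(d)
    est, saturated = decode(lev)
    tag = " (saturated)" if saturated else ""
    print(f"{d:14.2f} {lev.left:10.1f} {lev.right:11.1f} {est:12.2f}{tag}")

print()
print("Interaural difference grows at 2 x 25 dB/m, so a listener who has")
print("learned the rule can read lateral position off the stereo balance;")
print("beyond |d| = 2 m an ear clamps and the decoded value saturates.")
lev = BinauralLevel(-25.0, -75.0)
print(f"decode({lev.left}, {lev.right}) = {decode(lev)[0]:+.2f} m")
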