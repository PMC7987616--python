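"""Encrypting an extracted dataset with a password.

Datasets leaving a safe haven are encrypted with AES-256 (CTR mode with
HMAC-SHA256 authentication, password-derived keys). Decryption with the
wrong password raises — it never yields silent garbage.
"""
from ehrcohort import (AuthenticationError, StudyDesign, decrypt_output,
                       encrypt_output, extract, worked_toy, worked_toy_design)
from ehrcohort.stage6 import write_dataset

result = extract(worked_toy(), StudyDesign.model_validate(worked_toy_design()))
plain = write_dataset(result.dataset, None)

container = encrypt_output(plain, "correct-password")
print(f"dataset: {len(plain)} bytes -> encrypted container: {len(container)} bytes")

recovered = decrypt_output(container, "correct-password")
print(f"round-trip identical: {recovered == plain}")

try:
    decrypt_output(container, "wrong-password")
except AuthenticationError as exc:
    print(f"wrong password: {type(exc).__name__}: {exc}")
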