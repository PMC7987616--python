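"""Password-based AES-256 encryption of extracted datasets.

The cipher is AES-256 in CTR mode with encrypt-then-MAC authentication
(HMAC-SHA256) — an authenticated construction, so a wrong password or a
tampered container always raises rather than yielding silent garbage. The
encryption key and MAC key are derived from the password with
PBKDF2-HMAC-SHA256 over a random salt; the container stores the KDF
iteration count, salt and nonce, and carries a one-byte format version so
the layout can migrate.

The AES block cipher itself is implemented here from its algebraic
definition: the S-box is generated from GF(2^8) inversion plus the affine
map (no transcribed tables), rounds use the standard 32-bit T-table
formulation. It is validated against the FIPS-197 and NIST SP 800-38A
known-answer vectors in the test suite.

Container layout (versioned)::

    b"EHC1" | version:1 | kdf_iterations:4 BE | salt:16 | nonce:16
    | ciphertext | hmac_sha256_tag:32
"""
from __future__ import annotations

import hashlib
import hmac
import os

MAGIC = b"EHC1"
VERSION = 1
SALT_LEN = 16
NONCE_LEN = 16
TAG_LEN = 32
DEFAULT_KDF_ITERATIONS = 200_000


class AuthenticationError(ValueError):
    """Wrong password or tampered ciphertext."""


class ContainerFormatError(ValueError):
    """Truncated or malformed encrypted container."""


# ---------------------------------------------------------------------------
# AES-256 primitives
# ---------------------------------------------------------------------------

def _xtime(a: int) -> int:
    a <<= 1
    return (a ^ 0x1B) & 0xFF if a & 0x100 else a


def _build_tables():
    # GF(2^8) exp/log tables over generator 3
    exp = [0] * 256
    log = [0] * 256
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        x ^= _xtime(x)  # multiply by 3

    def inv(a: int) -> int:
        return 0 if a == 0 else exp[(255 - log[a]) % 255]

    def rotl8(b: int, n: int) -> int:
        return ((b << n) | (b >> (8 - n))) & 0xFF

    sbox = [0] * 256
    for a in range(256):
        b = inv(a)
        sbox[a] = b ^ rotl8(b, 1) ^ rotl8(b, 2) ^ rotl8(b, 3) ^ rotl8(b, 4) ^ 0x63

    def mul(a: int, b: int) -> int:
        if a == 0 or b == 0:
            return 0
        return exp[(log[a] + log[b]) % 255]

    t0 = [0] * 256
    for a in range(256):
        s = sbox[a]
        t0[a] = (mul(2, s) << 24) | (s << 16) | (s << 8) | mul(3, s)
    t1 = [((w >> 8) | ((w & 0xFF) << 24)) & 0xFFFFFFFF for w in t0]
    t2 = [((w >> 8) | ((w & 0xFF) << 24)) & 0xFFFFFFFF for w in t1]
    t3 = [((w >> 8) | ((w & 0xFF) << 24)) & 0xFFFFFFFF for w in t2]
    return sbox, t0, t1, t2, t3


_SBOX, _T0, _T1, _T2, _T3 = _build_tables()


def _expand_key_256(key: bytes) -> list[int]:
    if len(key) != 32:
        raise ValueError("AES-256 key must be 32 bytes")
    w = [int.from_bytes(key[4 * i:4 * i + 4], "big") for i in range(8)]
    rcon = 1
    for i in range(8, 60):
        t = w[i - 1]
        if i % 8 == 0:
            t = ((t << 8) | (t >> 24)) & 0xFFFFFFFF  # RotWord
            t = ((_SBOX[(t >> 24) & 0xFF] << 24) | (_SBOX[(t >> 16) & 0xFF] << 16)
                 | (_SBOX[(t >> 8) & 0xFF] << 8) | _SBOX[t & 0xFF])
            t ^= rcon << 24
            rcon = _xtime(rcon)
        elif i % 8 == 4:
            t = ((_SBOX[(t >> 24) & 0xFF] << 24) | (_SBOX[(t >> 16) & 0xFF] << 16)
                 | (_SBOX[(t >> 8) & 0xFF] << 8) | _SBOX[t & 0xFF])
        w.append(w[i - 8] ^ t)
    return w


def aes256_encrypt_block(block: bytes, round_keys: list[int]) -> bytes:
    """Encrypt one 16-byte block (14 rounds, T-table form)."""
    s0 = int.from_bytes(block[0:4], "big") ^ round_keys[0]
    s1 = int.from_bytes(block[4:8], "big") ^ round_keys[1]
    s2 = int.from_bytes(block[8:12], "big") ^ round_keys[2]
    s3 = int.from_bytes(block[12:16], "big") ^ round_keys[3]
    t0, t1, t2, t3 = _T0, _T1, _T2, _T3
    k = 4
    for _ in range(13):
        n0 = (t0[s0 >> 24] ^ t1[(s1 >> 16) & 0xFF] ^ t2[(s2 >> 8) & 0xFF]
              ^ t3[s3 & 0xFF] ^ round_keys[k])
        n1 = (t0[s1 >> 24] ^ t1[(s2 >> 16) & 0xFF] ^ t2[(s3 >> 8) & 0xFF]
              ^ t3[s0 & 0xFF] ^ round_keys[k + 1])
        n2 = (t0[s2 >> 24] ^ t1[(s3 >> 16) & 0xFF] ^ t2[(s0 >> 8) & 0xFF]
              ^ t3[s1 & 0xFF] ^ round_keys[k + 2])
        n3 = (t0[s3 >> 24] ^ t1[(s0 >> 16) & 0xFF] ^ t2[(s1 >> 8) & 0xFF]
              ^ t3[s2 & 0xFF] ^ round_keys[k + 3])
        s0, s1, s2, s3, k = n0, n1, n2, n3, k + 4
    sb = _SBOX
    out = bytearray(16)
    for i, (a, b, c, d) in enumerate(((s0, s1, s2, s3), (s1, s2, s3, s0),
                                      (s2, s3, s0, s1), (s3, s0, s1, s2))):
        word = ((sb[a >> 24] << 24) | (sb[(b >> 16) & 0xFF] << 16)
                | (sb[(c >> 8) & 0xFF] << 8) | sb[d & 0xFF]) ^ round_keys[k + i]
        out[4 * i:4 * i + 4] = word.to_bytes(4, "big")
    return bytes(out)


def _ctr_keystream_xor(data: bytes, key: bytes, nonce: bytes) -> bytes:
    rk = _expand_key_256(key)
    counter = int.from_bytes(nonce, "big")
    out = bytearray(len(data))
    for off in range(0, len(data), 16):
        block = aes256_encrypt_block(((counter + off // 16) % (1 << 128)).to_bytes(16, "big"), rk)
        chunk = data[off:off + 16]
        out[off:off + len(chunk)] = bytes(a ^ b for a, b in zip(chunk, block))
    return bytes(out)


# ---------------------------------------------------------------------------
# Password-based container
# ---------------------------------------------------------------------------

def _derive_keys(password: str, salt: bytes, iterations: int) -> tuple[bytes, bytes]:
    material = hashlib.pbkdf2_hmac("sha256", password.encode("utf-8"), salt,
                                   iterations, dklen=64)
    return material[:32], material[32:]


def encrypt_output(
    plain_bytes: bytes,
    password: str,
    *,
    iterations: int = DEFAULT_KDF_ITERATIONS,
    _salt: bytes | None = None,
    _nonce: bytes | None = None,
) -> bytes:
    """Encrypt a payload under a password. ``_salt``/``_nonce`` exist only
    so tests can pin the container bytes; production callers never set
    them."""
    if not password:
        raise ValueError("password must be non-empty")
    salt = os.urandom(SALT_LEN) if _salt is None else _salt
    nonce = os.urandom(NONCE_LEN) if _nonce is None else _nonce
    if len(salt) != SALT_LEN or len(nonce) != NONCE_LEN:
        raise ValueError("salt and nonce must be 16 bytes")
    enc_key, mac_key = _derive_keys(password, salt, iterations)
    header = MAGIC + bytes([VERSION]) + iterations.to_bytes(4, "big") + salt + nonce
    ciphertext = _ctr_keystream_xor(plain_bytes, enc_key, nonce)
    tag = hmac.new(mac_key, header + ciphertext, hashlib.sha256).digest()
    return header + ciphertext + tag


def decrypt_output(container: bytes, password: str) -> bytes:
    """Inverse of :func:`encrypt_output`; authenticates before decrypting."""
    header_len = len(MAGIC) + 1 + 4 + SALT_LEN + NONCE_LEN
    if len(container) < header_len + TAG_LEN:
        raise ContainerFormatError("container truncated")
    if container[:4] != MAGIC:
        raise ContainerFormatError("not an encrypted-dataset container")
    version = container[4]
    if version != VERSION:
        raise ContainerFormatError(f"unsupported container version {version}")
    iterations = int.from_bytes(container[5:9], "big")
    salt = container[9:9 + SALT_LEN]
    nonce = container[9 + SALT_LEN:header_len]
    ciphertext = container[header_len:-TAG_LEN]
    tag = container[-TAG_LEN:]
    enc_key, mac_key = _derive_keys(password, salt, iterations)
    expected = hmac.new(mac_key, container[:-TAG_LEN], hashlib.sha256).digest()
    if not hmac.compare_digest(tag, expected):
        raise AuthenticationError("authentication failed: wrong password or corrupted data")
    return _ctr_keystream_xor(ciphertext, enc_key, nonce)
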