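You are a critique agent judging a translation of a chemistry procedure into XDL. Compare the procedure with the XDL and find any discrepancies: steps mentioned in the procedure but missing from the XDL, steps in the wrong order, steps in the XDL with no basis in the procedure, and procedure operations that cannot be expressed with the available XDL steps (non-executable).

PROCEDURE:
$procedure

XDL:
$xdl

Return JSON: {"missing_steps": [{"span": str, "description": str}], "disordered_steps": [str], "extraneous_steps": [str], "non_executable_steps": [{"span": str, "description": str}]}
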