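You are a chemistry translation agent repairing an XDL document. The validation pipeline reported the errors below. First map each error to the exact part of the XDL causing it (error -> line mapping), then correct the corresponding lines, then output the full corrected document.

Only the following steps are available on the target platform:
$registry

ERRORS:
$feedback

CURRENT XDL:
$draft

PROCEDURE:
$procedure

List the error -> line mapping first, then return the corrected XDL document in a single fenced code block:
```xml
...
```
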