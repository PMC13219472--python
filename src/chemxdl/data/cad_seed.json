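{
  "_comment": "Synthetic seed for the chemical ambiguity database: procedure fragments paired with expert explanations of implicit chemical knowledge. Written for this package as a small non-canonical stand-in for an expert-annotated collection.",
  "entries": [
    {
      "fragment": "the mixture was heated to reflux",
      "explanation": "Reflux temperature equals the boiling point of the lowest-boiling solvent present; set the heating target to that boiling point, not an arbitrary high value."
    },
    {
      "fragment": "the flask was lifted halfway from the oil bath",
      "explanation": "Partially removing a vessel from a heat source reduces heat input; on a platform without bath manipulation, approximate by lowering the set temperature by roughly 10-20 degrees Celsius."
    },
    {
      "fragment": "added dropwise over the course of the addition",
      "explanation": "Dropwise addition limits heat or gas evolution; approximate as a slow timed transfer, by default 10 minutes, unless the text states a duration."
    },
    {
      "fragment": "the combined organic layers were dried and concentrated",
      "explanation": "Drying means stirring over an inert desiccant such as sodium sulfate followed by filtration; concentration means rotary evaporation under reduced pressure at moderate temperature."
    },
    {
      "fragment": "the pH was adjusted to neutral with dilute acid",
      "explanation": "Without inline pH control, estimate the required volume from the stated base quantity and add it as a normal addition; flag the step as approximate."
    },
    {
      "fragment": "the solution was allowed to warm to room temperature",
      "explanation": "Stop active cooling and hold at 20-25 degrees Celsius; on a temperature-controlled platform set the target to 20 degrees Celsius."
    },
    {
      "fragment": "extracted with ethyl acetate and washed with brine",
      "explanation": "Each extraction is a separation step transferring the organic phase; brine washes use saturated aqueous sodium chloride and are also separations."
    },
    {
      "fragment": "the residue was recrystallized from hot ethanol",
      "explanation": "Dissolve the crude solid in a minimal volume of near-boiling solvent, cool slowly to induce crystallization, then filter and dry the solid."
    }
  ]
}
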