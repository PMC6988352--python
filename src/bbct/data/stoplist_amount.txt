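any
some
part
number
amount
frequency
type
pattern
class
group
range
change
increase
decrease
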