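item,rating
Q1,5
Q1,5
Q1,6
Q2,5
Q2,6
Q2,6
Q3,4
Q3,6
Q3,6
Q4,4
Q4,6
Q4,6
Q5,5
Q5,5
Q5,5
Q6,3
Q6,4
Q6,6
Q7,3
Q7,6
Q7,6
Q8,3
Q8,6
Q8,6
Q9,4
Q9,5
Q9,6
Q10,4
Q10,5
Q10,6
Q11,6
Q11,6
Q11,6
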